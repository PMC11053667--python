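"""Deming regression and Bland-Altman agreement statistics."""

import math

import numpy as np
import pytest

from dbstdm import Analyte, bland_altman, compare_dbs_plasma, deming_fit
from dbstdm.errors import DomainError, InsufficientDataError


def deming_objective(x, y, slope, intercept, lam=1.0):
    """Sum of error-weighted orthogonal deviations for the Deming model."""
    return np.sum((y - intercept - slope * x) ** 2 / (lam + slope**2))


def grid_search_deming(x, y, lam=1.0):
    """Independent brute-force minimiser of the Deming objective, refined to 1e-4."""
    b_lo, b_hi = -5.0, 5.0
    a_lo, a_hi = -10.0, 10.0
    best = (None, None)
    for _ in range(5):  # successive 81x81 refinements: final cell < 1e-4
        bs = np.linspace(b_lo, b_hi, 81)
        as_ = np.linspace(a_lo, a_hi, 81)
        bg, ag = np.meshgrid(bs, as_)
        obj = np.array(
            [[deming_objective(x, y, b, a, lam) for b in bs] for a in as_]
        )
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        best = (bs[j], as_[i])
        db, da = (b_hi - b_lo) / 80, (a_hi - a_lo) / 80
        b_lo, b_hi = bs[j] - db, bs[j] + db
        a_lo, a_hi = as_[i] - da, as_[i] + da
    return best


class TestDeming:
    def test_identity_data(self):
        x = [1.0, 2.5, 4.0, 8.0]
        fit = deming_fit(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    @pytest.mark.parametrize("weighting", ["none", "inverse_squared_mean"])
    def test_exact_half_slope(self, weighting):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        fit = deming_fit(x, 0.5 * x, weighting=weighting)
        assert fit.slope == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self, rng):
        x = rng.uniform(1, 10, 8)
        y = 1.3 * x + 0.4 + rng.normal(0, 0.6, 8)
        fit = deming_fit(x, y, weighting="none")
        b, a = grid_search_deming(x, y)
        assert fit.slope == pytest.approx(b, abs=2e-4)
        assert fit.intercept == pytest.approx(a, abs=2e-4)

    def test_lambda_infinity_is_ols(self, rng):
        x = rng.uniform(1, 10, 25)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.5, 25)
        fit = deming_fit(x, y, lam=1e8)
        b, a = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(b, abs=1e-6)
        assert fit.intercept == pytest.approx(a, abs=1e-5)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(1, 10, 12)
        y = 0.8 * x + rng.normal(0, 0.2, 12)
        base = deming_fit(x, y, lam=1.0)
        # scaling y by c scales the slope by c once lambda tracks the error
        # variances (var of c*y errors is c^2 * var of y errors)
        c = 3.0
        scaled = deming_fit(x, c * y, lam=c**2)
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-9)

    def test_degenerate_data(self):
        with pytest.raises(DomainError):
            deming_fit([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])

    def test_weighted_requires_positive(self):
        with pytest.raises(DomainError):
            deming_fit([0.0, 1.0, 2.0], [1.0, 2.0, 3.0],
                       weighting="inverse_squared_mean")

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            deming_fit([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_perfect_agreement(self):
        a = [1.0, 2.0, 3.0]
        res = bland_altman(a, a)
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.mean_diff == pytest.approx(1.0)
        assert res.sd_diff == 0.0
        assert res.ci_mean_diff == (pytest.approx(1.0), pytest.approx(1.0))

    def test_two_point_hand_arithmetic(self):
        res = bland_altman([1.0, 3.0], [1.0, 1.0])  # diffs {0, 2}
        assert res.mean_diff == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(math.sqrt(2.0))
        assert res.loa_low == pytest.approx(1.0 - 1.96 * math.sqrt(2.0))
        assert res.loa_high == pytest.approx(1.0 + 1.96 * math.sqrt(2.0))

    def test_antisymmetry(self, rng):
        a = rng.uniform(1, 10, 15)
        b = rng.uniform(1, 10, 15)
        assert bland_altman(a, b).mean_diff == pytest.approx(
            -bland_altman(b, a).mean_diff
        )

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])


class TestCompareDbsPlasma:
    def test_noise_free_conversion_is_exact(self, noise_free_records):
        records, _ = noise_free_records
        for analyte in Analyte:
            rep = compare_dbs_plasma(records, analyte, k_source="fit")
            assert rep.deming_converted.slope == pytest.approx(1.0, abs=1e-8)
            assert rep.deming_converted.intercept == pytest.approx(0.0, abs=1e-8)
            assert rep.ba_converted.mean_diff == pytest.approx(0.0, abs=1e-8)

    def test_metabolite_raw_slope_tracks_one_minus_hct(self):
        """With K=0 the blood/plasma ratio is 1-Hct, so the raw Deming slope
        should sit near the cohort mean of (1-Hct)."""
        from dbstdm.synthetic import (
            SyntheticConfig, generate_cohort, generate_paired, paired_records,
        )
        cfg = SyntheticConfig(seed=21, n_subjects=60, meas_cv=0.05)
        records = paired_records(generate_paired(generate_cohort(cfg), cfg))
        rep = compare_dbs_plasma(records, Analyte.METABOLITE, k_source="fixed:0")
        hct = np.array([r.hct for r in records if r.analyte == Analyte.METABOLITE])
        expected = float(np.mean(1.0 - hct))
        assert rep.deming_raw.slope_ci[0] <= expected <= rep.deming_raw.slope_ci[1]

    def test_fixed_k_string_and_float_agree(self, noise_free_records):
        records, _ = noise_free_records
        a = compare_dbs_plasma(records, Analyte.PARENT, k_source="fixed:1.57")
        b = compare_dbs_plasma(records, Analyte.PARENT, k_source=1.57)
        assert a.k_used == b.k_used == 1.57
        assert a.partition is None

    def test_insufficient_records(self):
        from dbstdm import PairedMeasurement, Timepoint
        recs = [
            PairedMeasurement("1", Analyte.PARENT, Timepoint.TROUGH, 1.0, 1.0, 0.4),
            PairedMeasurement("2", Analyte.PARENT, Timepoint.TROUGH, 2.0, 2.0, 0.4),
        ]
        with pytest.raises(InsufficientDataError):
            compare_dbs_plasma(recs, Analyte.PARENT)
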