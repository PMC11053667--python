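"""Calibration fitting and the method-validation statistic suite."""

import numpy as np
import pandas as pd
import pytest

from dbstdm import (
    Analyte,
    CAL_LEVELS,
    CalibrationObservation,
    back_calculate,
    fit_calibration,
    hct_effect,
    lloq_check,
    matrix_effect_slopes,
    qc_stats,
    recovery,
    stability_ratios,
    volume_effect,
)
from dbstdm.errors import DesignError, DomainError, InsufficientDataError


def _exact_obs(slope, intercept, levels=CAL_LEVELS, analyte=Analyte.PARENT):
    return [
        CalibrationObservation(analyte, c, slope * c + intercept)
        for c in levels
    ]


class TestCalibration:
    def test_exact_line_recovers_published_parameters(self):
        """The parent-drug assay line (slope 0.1683, intercept -0.0012 response
        ratio per µg/mL) is recovered exactly from noise-free responses."""
        curve = fit_calibration(_exact_obs(0.1683, -0.0012))
        assert curve.slope == pytest.approx(0.1683, rel=1e-10)
        assert curve.intercept == pytest.approx(-0.0012, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery_generic(self, rng):
        slope, intercept = rng.uniform(0.05, 2.0), rng.uniform(-0.01, 0.05)
        curve = fit_calibration(_exact_obs(slope, intercept))
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-12)

    def test_flat_responses_rejected(self):
        obs = [
            CalibrationObservation(Analyte.PARENT, c, 1.0) for c in CAL_LEVELS
        ]
        with pytest.raises(DesignError):
            fit_calibration(obs)

    def test_too_few_levels_rejected(self):
        with pytest.raises(DesignError):
            fit_calibration(_exact_obs(0.2, 0.0, levels=(0.1, 1, 5, 10, 20)))

    def test_weighted_option_exact_on_line(self):
        curve = fit_calibration(_exact_obs(0.5, 0.01), weighting="1/x2")
        assert curve.slope == pytest.approx(0.5, rel=1e-10)

    def test_back_calculate_round_trip(self):
        curve = fit_calibration(_exact_obs(0.1683, -0.0012))
        for c in CAL_LEVELS:
            assert back_calculate(curve, curve.predict(c)) == pytest.approx(
                c, rel=1e-10
            )
        assert back_calculate(curve, curve.intercept) == pytest.approx(0.0, abs=1e-12)

    def test_back_calculate_simple(self):
        curve = fit_calibration(_exact_obs(2.0, 0.0))
        assert back_calculate(curve, 5.0) == pytest.approx(2.5)


class TestLloq:
    def test_published_lloq_passes(self):
        """CV 19.2 %, accuracy 102 % and a 6-fold signal ratio meet the
        20 %/5-fold acceptance rule."""
        # three replicates around nominal 0.1 with CV 19.2% and mean 0.102
        mean, cv = 0.102, 19.2
        sd = cv / 100 * mean
        reps = [mean - sd, mean, mean + sd]
        res = lloq_check(reps, nominal=0.1, blank_signal=1.0, lloq_signal=6.0)
        assert res.passed
        assert res.cv_pct == pytest.approx(19.2, rel=1e-6)
        assert res.bias_pct == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize(
        "reps, blank, sig, passed",
        [
            ([0.08, 0.10, 0.13], 1.0, 6.0, False),   # CV > 20%
            ([0.099, 0.1, 0.101], 1.0, 4.9, False),  # signal ratio < 5
            ([0.099, 0.1, 0.101], 0.0, 1.0, True),   # zero blank: infinite ratio
        ],
    )
    def test_threshold_rules(self, reps, blank, sig, passed):
        assert lloq_check(reps, 0.1, blank, sig).passed is passed


class TestQcStats:
    def test_inter_day_pools_replicates(self):
        rows = []
        rng = np.random.default_rng(1)
        for day in (1, 2, 3):
            for rep in range(5):
                rows.append(
                    {"analyte": "PARENT", "level": 3.0, "day": day,
                     "found": 3.11 * rng.lognormal(0, 0.0)}
                )
        stats = qc_stats(pd.DataFrame(rows))
        inter = [s for s in stats if s.scope == "inter_day"][0]
        assert inter.n == 15
        assert inter.bias_pct == pytest.approx(100 * (3.11 - 3.0) / 3.0)
        assert inter.cv_pct == 0.0

    def test_exact_found_is_zero_bias_cv(self):
        df = pd.DataFrame(
            {"analyte": "PARENT", "level": [3.0] * 5, "day": 1, "found": [3.0] * 5}
        )
        s = qc_stats(df)[0]
        assert s.bias_pct == 0.0 and s.cv_pct == 0.0

    def test_hand_computed_cv(self):
        df = pd.DataFrame(
            {"analyte": "PARENT", "level": [3.0, 3.0], "day": 1, "found": [2.0, 4.0]}
        )
        s = qc_stats(df)[0]
        assert s.mean_found == pytest.approx(3.0)
        assert s.bias_pct == pytest.approx(0.0)
        assert s.cv_pct == pytest.approx(100 * np.sqrt(2) / 3, rel=1e-9)  # 47.14

    def test_translation_consistency(self, rng):
        found = rng.uniform(2.5, 3.5, 10)
        base = pd.DataFrame(
            {"analyte": "PARENT", "level": 3.0, "day": 1, "found": found}
        )
        shifted = base.assign(found=found + 0.3)
        b = qc_stats(base)[0].bias_pct
        s = qc_stats(shifted)[0].bias_pct
        assert s - b == pytest.approx(100 * 0.3 / 3.0, rel=1e-9)

    def test_nonpositive_nominal_rejected(self):
        df = pd.DataFrame(
            {"analyte": "PARENT", "level": [0.0, 0.0], "day": 1, "found": [1.0, 1.0]}
        )
        with pytest.raises(DomainError):
            qc_stats(df)


class TestEffects:
    def test_matrix_effect_rsd(self):
        curves = [fit_calibration(_exact_obs(s, 0.0)) for s in (1.0, 1.1, 1.2, 1.3, 1.4)]
        rsd, ok = matrix_effect_slopes(curves)
        assert rsd == pytest.approx(100 * np.std([1, 1.1, 1.2, 1.3, 1.4], ddof=1) / 1.2)
        assert rsd == pytest.approx(13.18, abs=0.01)
        assert not ok
        identical = [fit_calibration(_exact_obs(0.2, 0.0)) for _ in range(5)]
        rsd0, ok0 = matrix_effect_slopes(identical)
        assert rsd0 == 0.0 and ok0

    def test_matrix_effect_three_percent_passes(self):
        slopes = np.array([0.97, 1.0, 1.03]) * 0.1683
        rsd, ok = matrix_effect_slopes([fit_calibration(_exact_obs(s, 0.0)) for s in slopes])
        assert rsd == pytest.approx(3.0, abs=0.1)
        assert ok

    def test_recovery(self):
        assert recovery(1.0, 1.0) == 100.0
        assert recovery(0.95, 1.0) == pytest.approx(95.0)
        with pytest.raises(DomainError):
            recovery(1.0, 0.0)

    def test_hct_effect_cells_and_verdicts(self):
        rows = []
        for hct in (25, 55):
            for level in (0.3, 3.0):
                for v in (1.0, 1.0, 1.0):
                    # 55%/0.3 cell biased +13.45%, tiny spread: passes the 15% band
                    bias = 0.1345 if (hct == 55 and level == 0.3) else 0.0
                    rows.append({"hct": hct, "level": level,
                                 "found": level * (1 + bias) * v})
        table = hct_effect(pd.DataFrame(rows))
        cell = table[(table.condition == 55) & (table.level == 0.3)].iloc[0]
        assert cell.bias_pct == pytest.approx(13.45, abs=0.01)
        assert cell.passed
        assert table[(table.condition == 25)].passed.all()

    def test_hct_effect_threshold_fail(self):
        rows = [
            {"hct": h, "level": 3.0, "found": 3.0 * (1.151 if h == 55 else 1.0)}
            for h in (25, 35, 45, 55) for _ in range(3)
        ]
        table = hct_effect(pd.DataFrame(rows))
        assert not table[table.condition == 55].passed.iloc[0]
        # independent recount of every verdict
        recomputed = (table.bias_pct.abs() <= 15.0) & (table.cv_pct <= 15.0)
        assert (table.passed == recomputed).all()

    def test_volume_effect(self):
        df = pd.DataFrame(
            {"volume": [10, 10, 20, 20, 30, 30], "ratio": [1.0] * 6}
        )
        out = volume_effect(df)
        assert out.attrs["overall_cv_pct"] == 0.0
        assert (out.pct_of_reference == 100.0).all()

    def test_volume_effect_reference_required(self):
        with pytest.raises(DesignError):
            volume_effect(pd.DataFrame({"volume": [20, 20], "ratio": [1.0, 1.0]}))
        with pytest.raises(DesignError):
            volume_effect(pd.DataFrame({"volume": [10, 10], "ratio": [1.0, 1.0]}))

    def test_stability_ratios(self):
        fresh = pd.DataFrame({"level": [0.3, 15.0], "found": [0.3, 15.0]})
        stored = pd.DataFrame(
            {
                "condition": ["28d_25C"] * 2 + ["5d_-20C"] * 2,
                "level": [0.3, 15.0, 0.3, 15.0],
                "found": [0.3 * 0.892, 15.0 * 0.933, 0.3 * 0.849, 15.0],
            }
        )
        table = stability_ratios(stored, fresh)
        cell_28 = table[(table.condition == "28d_25C") & (table.level == 0.3)].iloc[0]
        assert cell_28.pct_remaining == pytest.approx(89.2)
        assert cell_28.passed  # within 85-115
        cell_bad = table[(table.condition == "5d_-20C") & (table.level == 0.3)].iloc[0]
        assert cell_bad.pct_remaining == pytest.approx(84.9)
        assert not cell_bad.passed

    def test_stability_identity(self):
        fresh = pd.DataFrame({"level": [3.0], "found": [3.0]})
        stored = pd.DataFrame({"condition": ["x"], "level": [3.0], "found": [3.0]})
        assert stability_ratios(stored, fresh).pct_remaining.iloc[0] == 100.0

    def test_matrix_effect_needs_three_lots(self):
        with pytest.raises(InsufficientDataError):
            matrix_effect_slopes([fit_calibration(_exact_obs(0.2, 0.0))] * 2)
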