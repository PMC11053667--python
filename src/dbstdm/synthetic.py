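"""Seeded synthetic-data generator for every pipeline input.

The generator emulates a steady-state trough-monitoring cohort of adult
patients on 100-400 mg/day of the parent drug: haematocrit is normal
(mean 0.42, SD 0.05) truncated to the clinically plausible 0.25-0.55 band;
trough plasma concentrations follow a one-compartment steady-state
proportionality (concentration = dose / apparent clearance with lognormal
between-subject clearance); the metabolite tracks the parent through a
lognormal metabolite-to-parent ratio centred at 0.32; blood concentrations
derive from plasma via the partition relation with K = 1.57 for the parent and
K = 0 for the glucuronide; and every measured value carries independent
multiplicative lognormal error with a 5 % CV, the near-constant-CV behaviour of
an LC-MS/MS assay. Calibration responses are linear in concentration at the 11
assay levels with per-lot slope variation (2 % RSD).

All randomness flows from one ``numpy.random.Generator`` seeded in the config;
no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CAL_LEVELS,
    QC_LEVELS,
    Analyte,
    CalibrationObservation,
    PairedMeasurement,
    Timepoint,
)
from .errors import ConfigError
from .partition import blood_from_plasma

#: Daily doses observed in the reference cohort, mg/day.
DOSES = (100, 200, 250, 300, 400)

#: Apparent clearance scale linking dose (mg/day) to trough plasma conc
#: (µg/mL): 233 mg/day on average yields ~4.5 µg/mL.
_CLEARANCE_SCALE = 52.0


@dataclass
class SyntheticConfig:
    """Study conditions for the generator. Defaults are the conditions the
    analysis assumes; change them to stress-test, not to tune results."""

    seed: int = 0
    n_subjects: int = 9
    hct_mean: float = 0.42
    hct_sd: float = 0.05
    hct_bounds: tuple[float, float] = (0.25, 0.55)
    k_parent: float = 1.57
    k_metabolite: float = 0.0
    meas_cv: float = 0.05
    cal_slope: dict = field(
        default_factory=lambda: {Analyte.PARENT: 0.1683, Analyte.METABOLITE: 1.1243}
    )
    cal_intercept: dict = field(
        default_factory=lambda: {Analyte.PARENT: -0.0012, Analyte.METABOLITE: 0.0124}
    )
    lot_slope_rsd: float = 0.02
    mpr_location: float = 0.32
    mpr_log_sd: float = 0.45
    clearance_log_sd: float = 0.30
    conc_bounds: tuple[float, float] = (0.1, 20.0)
    outlier_spec: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("hct_sd", "meas_cv", "lot_slope_rsd", "mpr_log_sd", "clearance_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.hct_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("hct_bounds must lie within (0, 1)")
        if self.k_parent < 0 or self.k_metabolite < 0:
            raise ConfigError("partition coefficients must be >= 0")
        for idx, fold in self.outlier_spec:
            if fold <= 0:
                raise ConfigError("outlier fold-change must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _mult_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a subject cohort: dose, haematocrit, true trough plasma
    concentrations and the true metabolite-to-parent ratio.

    ``outlier_spec`` entries ``(subject_index, fold)`` multiply that subject's
    MPR by the clearance fold-change after the base draw, emulating enzyme
    induction (fold > 1) or inhibition (fold < 1).
    """
    rng = config.rng() if rng is None else rng
    n = config.n_subjects
    for idx, _ in config.outlier_spec:
        if not (0 <= idx < n):
            raise ConfigError(f"outlier subject index {idx} out of range [0, {n})")

    dose = rng.choice(DOSES, size=n)
    hct = _truncated_normal(
        rng, config.hct_mean, config.hct_sd, *config.hct_bounds, size=n
    )
    clearance = _CLEARANCE_SCALE * rng.lognormal(
        -(config.clearance_log_sd**2) / 2.0, config.clearance_log_sd, size=n
    )
    parent = np.clip(dose / clearance, *config.conc_bounds)
    mpr = config.mpr_location * rng.lognormal(
        -(config.mpr_log_sd**2) / 2.0, config.mpr_log_sd, size=n
    )
    for idx, fold in config.outlier_spec:
        mpr[idx] *= fold
    return pd.DataFrame(
        {
            "subject_id": [str(i + 1) for i in range(n)],
            "dose": dose,
            "hct": hct,
            "parent_cpl_true": parent,
            "metabolite_cpl_true": mpr * parent,
            "mpr_true": mpr,
        }
    )


def generate_paired(
    cohort: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Turn a cohort into per-analyte paired blood/plasma measurements.

    True blood concentrations come from the partition relation with the
    analyte's K; observed blood and plasma values are the truth times
    independent unit-mean lognormal noise at ``meas_cv``. Columns ``c_b_true``
    and ``c_pl_true`` are retained for oracle checks.
    """
    if cohort.empty:
        raise ConfigError("cohort is empty")
    rng = config.rng() if rng is None else rng
    frames = []
    for analyte, conc_col, k in (
        (Analyte.PARENT, "parent_cpl_true", config.k_parent),
        (Analyte.METABOLITE, "metabolite_cpl_true", config.k_metabolite),
    ):
        cpl = cohort[conc_col].to_numpy(dtype=float)
        hct = cohort["hct"].to_numpy(dtype=float)
        cb = blood_from_plasma(cpl, hct, k)
        n = len(cohort)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"].to_numpy(),
                    "analyte": analyte.value,
                    "timepoint": Timepoint.TROUGH.value,
                    "hct": hct,
                    "c_b_true": cb,
                    "c_pl_true": cpl,
                    "c_b": cb * _mult_noise(rng, config.meas_cv, n),
                    "c_pl": cpl * _mult_noise(rng, config.meas_cv, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def paired_records(df: pd.DataFrame) -> list[PairedMeasurement]:
    """Convert a generated paired table into validated records."""
    return [
        PairedMeasurement(
            subject_id=str(r.subject_id),
            analyte=Analyte(r.analyte),
            timepoint=Timepoint(r.timepoint),
            c_b=float(r.c_b),
            c_pl=float(r.c_pl),
            hct=float(r.hct),
        )
        for r in df.itertuples(index=False)
    ]


def generate_calibration_run(
    config: SyntheticConfig,
    n_lots: int = 1,
    n_days: int = 3,
    levels: Sequence[float] = CAL_LEVELS,
    rng: np.random.Generator | None = None,
) -> list[CalibrationObservation]:
    """Calibration responses at the assay's levels for each lot x day x analyte.

    Each lot draws its own slope (RSD ``lot_slope_rsd`` around the configured
    slope, emulating relative matrix effects); responses then carry the usual
    multiplicative measurement noise.
    """
    if n_lots < 1:
        raise ConfigError("n_lots must be >= 1")
    rng = config.rng() if rng is None else rng
    levels = np.asarray(levels, dtype=float)
    obs: list[CalibrationObservation] = []
    for analyte in Analyte:
        slope0 = config.cal_slope[analyte]
        intercept = config.cal_intercept[analyte]
        for lot_i in range(n_lots):
            lot_slope = slope0 * (
                1.0 + rng.normal(0.0, config.lot_slope_rsd) if config.lot_slope_rsd > 0 else 1.0
            )
            for day in range(1, n_days + 1):
                noise = _mult_noise(rng, config.meas_cv, levels.size)
                resp = np.maximum(lot_slope * levels + intercept, 0.0) * noise
                for lev, r in zip(levels, resp):
                    obs.append(
                        CalibrationObservation(
                            analyte=analyte,
                            nominal_conc=float(lev),
                            response_ratio=float(r),
                            day=day,
                            lot=f"lot{lot_i + 1}",
                        )
                    )
    return obs


def generate_qc_run(
    config: SyntheticConfig,
    levels: Sequence[float] = QC_LEVELS,
    n_reps: int = 5,
    n_days: int = 3,
    level_bias: dict | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Found-concentration QC table: found = nominal * noise * (1 + bias).

    ``level_bias`` maps nominal level -> fractional bias (e.g. 0.037 for
    +3.7 %), emulating the small level-dependent accuracy offsets a validated
    assay exhibits; default no bias.
    """
    rng = config.rng() if rng is None else rng
    level_bias = level_bias or {}
    rows = []
    for analyte in Analyte:
        for level in levels:
            bias = level_bias.get(level, 0.0)
            for day in range(1, n_days + 1):
                noise = _mult_noise(rng, config.meas_cv, n_reps)
                for rep in range(1, n_reps + 1):
                    rows.append(
                        {
                            "analyte": analyte.value,
                            "level": float(level),
                            "day": day,
                            "replicate": rep,
                            "found": float(level) * (1.0 + bias) * noise[rep - 1],
                        }
                    )
    return pd.DataFrame(rows)
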