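"""Bioanalytical method-validation statistics.

Implements the validation battery of a regulated DBS assay: calibration-curve
fitting with back-calculated bias, LLOQ acceptance, intra-/inter-day accuracy
and precision, recovery, relative matrix effect via between-lot calibration
slope RSD, haematocrit effect, spot-volume effect and storage stability.

Conventions: bias% = 100*(mean found - nominal)/nominal; CV% = 100*sd/mean with
the sample (n-1) standard deviation; calibration is non-weighted ordinary least
squares of the analyte/IS response ratio on nominal concentration (a 1/x^2
weighted option exists behind a flag, default off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Analyte, CalibrationObservation
from .errors import DesignError, DomainError, InsufficientDataError

MIN_CAL_LEVELS = 6  # guideline minimum number of non-zero standards


@dataclass
class CalibrationCurve:
    """Fitted line response_ratio = slope * conc + intercept for one run."""

    analyte: Analyte
    slope: float
    intercept: float
    r2: float
    day: int
    residuals: pd.DataFrame  # per-level back-calculated bias %

    def predict(self, conc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(conc, dtype=float)


def fit_calibration(
    obs: Sequence[CalibrationObservation], weighting: str = "none"
) -> CalibrationCurve:
    """Least-squares calibration fit over >= 6 distinct non-zero levels.

    ``weighting="1/x2"`` switches to 1/concentration^2 weighted least squares;
    the default is the non-weighted fit. Blank observations (nominal 0) are
    excluded from the regression.
    """
    std = [o for o in obs if o.nominal_conc > 0]
    if not std:
        raise DesignError("no non-blank calibration standards")
    analytes = {o.analyte for o in std}
    if len(analytes) != 1:
        raise DesignError("calibration observations mix analytes; fit one at a time")
    days = {o.day for o in std}
    day = days.pop() if len(days) == 1 else -1

    x = np.array([o.nominal_conc for o in std])
    y = np.array([o.response_ratio for o in std])
    if len(np.unique(x)) < MIN_CAL_LEVELS:
        raise DesignError(
            f"calibration needs >= {MIN_CAL_LEVELS} distinct levels, "
            f"got {len(np.unique(x))}"
        )

    if weighting == "1/x2":
        w = 1.0 / x**2
        sw = w.sum()
        xb, yb = (w @ x) / sw, (w @ y) / sw
        slope = float((w @ ((x - xb) * (y - yb))) / (w @ (x - xb) ** 2))
        intercept = float(yb - slope * xb)
    elif weighting == "none":
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    else:
        raise DomainError(f"unknown weighting '{weighting}'")

    if slope <= 0:
        raise DesignError(f"calibration slope must be > 0, got {slope:.4g}")

    pred = intercept + slope * x
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    back = (y - intercept) / slope
    residuals = (
        pd.DataFrame({"nominal_conc": x, "back_calculated": back})
        .assign(bias_pct=lambda d: 100.0 * (d.back_calculated - d.nominal_conc) / d.nominal_conc)
        .groupby("nominal_conc", as_index=False)
        .agg(mean_back=("back_calculated", "mean"), bias_pct=("bias_pct", "mean"))
    )
    return CalibrationCurve(
        analyte=analytes.pop() if analytes else std[0].analyte,
        slope=slope,
        intercept=intercept,
        r2=r2,
        day=day,
        residuals=residuals,
    )


def back_calculate(curve: CalibrationCurve, response_ratio) -> float | np.ndarray:
    """Invert the calibration: (ratio - intercept) / slope.

    May return negative values for sub-blank responses; callers flag these as
    below-LLOQ rather than clipping.
    """
    if curve.slope <= 0:
        raise DomainError("curve slope must be > 0")
    out = (np.asarray(response_ratio, dtype=float) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


@dataclass
class LloqResult:
    cv_pct: float
    bias_pct: float
    signal_ratio: float
    passed: bool


def lloq_check(
    replicates: Sequence[float],
    nominal: float,
    blank_signal: float,
    lloq_signal: float,
    max_bias_cv_pct: float = 20.0,
    min_signal_ratio: float = 5.0,
) -> LloqResult:
    """LLOQ acceptance: CV and |bias| <= 20 % and signal >= 5x the blank.

    A zero blank gives an infinite signal ratio, which passes the 5-fold rule.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 3:
        raise InsufficientDataError("LLOQ check needs >= 3 replicates")
    if nominal <= 0:
        raise DomainError("nominal must be > 0")
    mean = reps.mean()
    cv = 100.0 * reps.std(ddof=1) / mean
    bias = 100.0 * (mean - nominal) / nominal
    ratio = float("inf") if blank_signal == 0 else lloq_signal / blank_signal
    passed = cv <= max_bias_cv_pct and abs(bias) <= max_bias_cv_pct and ratio >= min_signal_ratio
    return LloqResult(float(cv), float(bias), float(ratio), bool(passed))


@dataclass
class QCStats:
    analyte: Analyte
    level: float
    scope: str  # "intra_day" or "inter_day"
    day: int | None
    n: int
    mean_found: float
    cv_pct: float
    bias_pct: float


def qc_stats(found: pd.DataFrame) -> list[QCStats]:
    """Accuracy/precision from a QC table with columns analyte, level, day, found.

    Emits one intra-day row per (analyte, level, day) with >= 2 replicates and,
    when replicates span >= 2 days, one inter-day row pooling every replicate
    value across days (not day means).
    """
    for col in ("analyte", "level", "day", "found"):
        if col not in found.columns:
            raise DomainError(f"QC table missing column '{col}'")
    if (found["level"] <= 0).any():
        raise DomainError("nominal QC level must be > 0")

    def _stats(vals: np.ndarray, nominal: float) -> tuple[float, float, float]:
        mean = float(vals.mean())
        cv = 100.0 * float(vals.std(ddof=1)) / mean
        bias = 100.0 * (mean - nominal) / nominal
        return mean, cv, bias

    def _analyte(v) -> Analyte:
        return v if isinstance(v, Analyte) else Analyte(str(v).upper())

    out: list[QCStats] = []
    for (analyte, level, day), grp in found.groupby(["analyte", "level", "day"]):
        vals = grp["found"].to_numpy(dtype=float)
        if vals.size < 2:
            continue
        mean, cv, bias = _stats(vals, float(level))
        out.append(
            QCStats(_analyte(analyte), float(level), "intra_day", int(day),
                    vals.size, mean, cv, bias)
        )
    for (analyte, level), grp in found.groupby(["analyte", "level"]):
        if grp["day"].nunique() < 2:
            continue
        vals = grp["found"].to_numpy(dtype=float)
        mean, cv, bias = _stats(vals, float(level))
        out.append(
            QCStats(_analyte(analyte), float(level), "inter_day", None,
                    vals.size, mean, cv, bias)
        )
    return out


def matrix_effect_slopes(
    curves: Sequence[CalibrationCurve], threshold_pct: float = 4.0
) -> tuple[float, bool]:
    """Relative matrix effect as the RSD of between-lot calibration slopes.

    The method is considered free of significant relative matrix effects when
    the slope RSD across >= 3 (ideally 5) independent matrix lots is below the
    threshold (default 4 %).
    """
    if len(curves) < 3:
        raise InsufficientDataError("matrix-effect check needs >= 3 lot curves")
    slopes = np.array([c.slope for c in curves])
    mean = slopes.mean()
    if mean <= 0:
        raise DomainError("mean calibration slope must be > 0")
    rsd = 100.0 * slopes.std(ddof=1) / mean
    return float(rsd), bool(rsd < threshold_pct)


def recovery(extracted_response: float, post_extraction_spiked_response: float) -> float:
    """Extraction recovery A/B x 100 %: analyte response from an extracted
    spiked sample over the response from a blank extract spiked afterwards."""
    if post_extraction_spiked_response <= 0:
        raise DomainError("post-extraction spiked response must be > 0")
    if extracted_response < 0:
        raise DomainError("extracted response must be >= 0")
    return 100.0 * extracted_response / post_extraction_spiked_response


def hct_effect(
    found: pd.DataFrame, bias_cv_limit_pct: float = 15.0
) -> pd.DataFrame:
    """Haematocrit effect table: bias% and CV% per (hct, level) cell.

    ``found`` needs columns hct, level, found (replicates long-form; nominal is
    the level). Each cell carries its threshold and a pass verdict
    (|bias| and CV within the limit). Missing cells are simply absent.
    """
    for col in ("hct", "level", "found"):
        if col not in found.columns:
            raise DomainError(f"Hct-effect table missing column '{col}'")
    if found["hct"].nunique() < 2:
        raise DesignError("Hct effect needs >= 2 haematocrit levels")
    rows = []
    for (hct, level), grp in found.groupby(["hct", "level"]):
        vals = grp["found"].to_numpy(dtype=float)
        mean = vals.mean()
        bias = 100.0 * (mean - float(level)) / float(level)
        cv = 100.0 * vals.std(ddof=1) / mean if vals.size > 1 else 0.0
        rows.append(
            {
                "factor": "HCT",
                "condition": hct,
                "level": float(level),
                "n": vals.size,
                "bias_pct": bias,
                "cv_pct": cv,
                "threshold_pct": bias_cv_limit_pct,
                "passed": abs(bias) <= bias_cv_limit_pct and cv <= bias_cv_limit_pct,
            }
        )
    return pd.DataFrame(rows)


def volume_effect(
    ratios: pd.DataFrame, reference_volume: float = 10.0
) -> pd.DataFrame:
    """Spot-volume effect from columns volume, ratio (replicate response ratios).

    Each volume's mean ratio is expressed as a percent of the reference-volume
    mean; the summary row reports the CV% of the per-volume means across all
    volumes (reference included).
    """
    for col in ("volume", "ratio"):
        if col not in ratios.columns:
            raise DomainError(f"volume table missing column '{col}'")
    vols = ratios["volume"].unique()
    if reference_volume not in vols:
        raise DesignError(f"reference volume {reference_volume} not present")
    if len(vols) < 2:
        raise DesignError("volume effect needs more than the reference volume")
    means = ratios.groupby("volume")["ratio"].mean()
    ref = means.loc[reference_volume]
    if ref <= 0:
        raise DomainError("reference mean ratio must be > 0")
    out = pd.DataFrame(
        {
            "factor": "VOLUME",
            "condition": means.index.to_numpy(),
            "mean_ratio": means.to_numpy(),
            "pct_of_reference": 100.0 * means.to_numpy() / ref,
        }
    )
    out.attrs["overall_cv_pct"] = float(
        100.0 * means.std(ddof=1) / means.mean()
    )
    return out


def stability_ratios(
    stored: pd.DataFrame, fresh: pd.DataFrame, limit_pct: float = 15.0
) -> pd.DataFrame:
    """Storage stability as percent remaining versus freshly prepared samples.

    ``stored`` has columns condition, level, found; ``fresh`` has level, found.
    %remaining = 100 * mean(stored) / mean(fresh) at the matched level; a cell
    passes when within 100 +/- limit.
    """
    for col in ("condition", "level", "found"):
        if col not in stored.columns:
            raise DomainError(f"stored table missing column '{col}'")
    fresh_means = fresh.groupby("level")["found"].mean()
    rows = []
    for (cond, level), grp in stored.groupby(["condition", "level"]):
        if level not in fresh_means.index:
            raise DomainError(f"no fresh reference at level {level}")
        ref = fresh_means.loc[level]
        if ref <= 0:
            raise DomainError("fresh reference concentration must be > 0")
        pct = 100.0 * grp["found"].mean() / ref
        rows.append(
            {
                "factor": "STABILITY",
                "condition": cond,
                "level": float(level),
                "pct_remaining": pct,
                "threshold_pct": limit_pct,
                "passed": abs(pct - 100.0) <= limit_pct,
            }
        )
    return pd.DataFrame(rows)
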