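"""Method-comparison statistics: weighted Deming regression and Bland-Altman.

Deming regression is the errors-in-variables line fit used when both the test
method (here DBS) and the comparator (plasma) carry measurement error. With
``lambda`` the ratio of the y-error variance to the x-error variance, the slope
has the closed form

    b = [S_yy - lambda S_xx + sqrt((S_yy - lambda S_xx)^2 + 4 lambda S_xy^2)]
        / (2 S_xy)

(lambda -> infinity recovers ordinary least squares of y on x; lambda = 1 is
orthogonal regression). The weighted variant downweights large concentrations
with w_i = 1 / ((x_i + y_i)/2)^2, the standard choice under proportional
(constant-CV) analytical error; weighted moments feed the same closed form and
the solution is iterated to a fixed point of the slope.

Confidence intervals for slope and intercept are leave-one-out jackknife with
t(n-1) quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .datamodel import Analyte, PairedMeasurement
from .errors import DomainError, InsufficientDataError
from .partition import PartitionFit, estimate_k, plasma_from_blood

Weighting = Literal["none", "inverse_squared_mean"]


@dataclass
class DemingFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    lam: float
    weighting: Weighting
    n: int


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_diff: tuple[float, float]
    n: int


def _deming_point(
    x: np.ndarray, y: np.ndarray, lam: float, w: np.ndarray
) -> tuple[float, float]:
    sw = w.sum()
    xb = float(w @ x) / sw
    yb = float(w @ y) / sw
    sxx = float(w @ (x - xb) ** 2) / sw
    syy = float(w @ (y - yb) ** 2) / sw
    sxy = float(w @ ((x - xb) * (y - yb))) / sw
    if sxx == 0.0 and syy == 0.0:
        raise DomainError("zero variance in both x and y: degenerate data")
    if sxy == 0.0:
        # no covariance: vertical/horizontal degenerate case
        raise DomainError("zero covariance between x and y: slope undefined")
    disc = (syy - lam * sxx) ** 2 + 4.0 * lam * sxy**2
    slope = (syy - lam * sxx + math.sqrt(disc)) / (2.0 * sxy)
    return slope, yb - slope * xb


def _deming_solve(
    x: np.ndarray, y: np.ndarray, lam: float, weighting: Weighting
) -> tuple[float, float]:
    if weighting == "none":
        w = np.ones_like(x)
        return _deming_point(x, y, lam, w)
    # proportional-error weights from the pairwise mean concentration;
    # iterate to a slope fixed point (converges immediately for data-based
    # weights, kept as a loop for robustness)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("weighted Deming requires strictly positive values")
    w = 1.0 / (((x + y) / 2.0) ** 2)
    slope, intercept = _deming_point(x, y, lam, w)
    for _ in range(50):
        new_slope, new_intercept = _deming_point(x, y, lam, w)
        if abs(new_slope - slope) < 1e-10:
            return new_slope, new_intercept
        slope, intercept = new_slope, new_intercept
    return slope, intercept


def deming_fit(
    x: Sequence[float],
    y: Sequence[float],
    lam: float = 1.0,
    weighting: Weighting = "none",
) -> DemingFit:
    """Fit y on x by (optionally weighted) Deming regression.

    ``lam`` is the ratio of the error variance of y to that of x (1 when both
    assays are assumed equally imprecise). Jackknife 95 % CIs are attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"Deming regression needs n >= 3, got {n}")
    if lam <= 0:
        raise DomainError("lambda must be > 0")

    slope, intercept = _deming_solve(x, y, lam, weighting)

    loo = np.empty((n, 2))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        loo[i] = _deming_solve(x[mask], y[mask], lam, weighting)
        mask[i] = True
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    tq = stats.t.ppf(0.975, n - 1)
    est = np.array([slope, intercept])
    lo = np.minimum(est - tq * se, est)
    hi = np.maximum(est + tq * se, est)
    return DemingFit(
        slope=slope,
        intercept=intercept,
        slope_ci=(float(lo[0]), float(hi[0])),
        intercept_ci=(float(lo[1]), float(hi[1])),
        lam=lam,
        weighting=weighting,
        n=n,
    )


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of method ``a`` against comparator ``b``.

    Differences are ``a - b``; limits of agreement are mean +/- 1.96 SD
    (sample SD, n-1) and the CI of the mean difference uses t(n-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("a and b must have equal length")
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2, got {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        ci_mean_diff=(mean - half, mean + half),
        n=n,
    )


@dataclass
class ComparisonReport:
    """The four-panel DBS-vs-plasma cross-validation for one analyte.

    ``deming_raw`` regresses the whole-blood concentration (response) on
    measured plasma — its slope is the blood-to-plasma concentration ratio.
    ``deming_converted`` regresses partition-converted plasma on measured
    plasma, where agreement means slope ~ 1, intercept ~ 0. The two
    Bland-Altman panels mirror those comparisons.
    """

    analyte: Analyte
    deming_raw: DemingFit
    deming_converted: DemingFit
    ba_raw: BlandAltmanResult
    ba_converted: BlandAltmanResult
    partition: PartitionFit | None
    k_used: float
    calculated_plasma: np.ndarray
    measured_plasma: np.ndarray
    blood: np.ndarray
    n: int


def compare_dbs_plasma(
    paired: Sequence[PairedMeasurement],
    analyte: Analyte,
    k_source: str | float = "fit",
    lam: float = 1.0,
    weighting: Weighting = "inverse_squared_mean",
) -> ComparisonReport:
    """Cross-validate DBS against plasma for one analyte.

    ``k_source`` is ``"fit"`` (estimate K from these records), a number, or a
    string ``"fixed:<value>"``. Only records with blood, plasma and
    haematocrit all present enter the comparison.
    """
    sel = [r for r in paired if r.analyte == analyte and r.complete]
    if len(sel) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete records for {analyte.label}, got {len(sel)}"
        )
    c_b = np.array([r.c_b for r in sel])
    c_pl = np.array([r.c_pl for r in sel])
    hct = np.array([r.hct for r in sel])

    fit: PartitionFit | None = None
    if isinstance(k_source, str) and k_source == "fit":
        fit = estimate_k(c_b=c_b, c_pl=c_pl, hct=hct)
        k = fit.k_bcpl
    elif isinstance(k_source, str) and k_source.startswith("fixed:"):
        k = float(k_source.split(":", 1)[1])
    else:
        k = float(k_source)

    calc = plasma_from_blood(c_b, hct, k)
    return ComparisonReport(
        analyte=analyte,
        deming_raw=deming_fit(c_pl, c_b, lam=lam, weighting=weighting),
        deming_converted=deming_fit(c_pl, calc, lam=lam, weighting=weighting),
        ba_raw=bland_altman(c_b, c_pl),
        ba_converted=bland_altman(calc, c_pl),
        partition=fit,
        k_used=k,
        calculated_plasma=calc,
        measured_plasma=c_pl,
        blood=c_b,
        n=len(sel),
    )
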