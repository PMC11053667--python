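"""Blood <-> plasma concentration conversion and partition-coefficient estimation.

A drug distributes between plasma and blood cells. With haematocrit ``Hct`` and
blood-cell-to-plasma partition coefficient ``K`` (ratio of the analyte
concentration in blood cells to that in plasma), whole-blood and plasma
concentrations are linked by

    c_B = c_PL * [(1 - Hct) + K * Hct]

so that a plasma concentration can be recovered from a DBS (whole-blood)
measurement as ``c_PL = c_B / ((1 - Hct) + K * Hct)``. ``K = 0`` (an analyte
confined to plasma, e.g. a glucuronide with no cell-membrane permeability)
reduces this to the plain haematocrit correction ``c_PL = c_B / (1 - Hct)``;
``K = 1`` makes blood and plasma concentrations identical.

``estimate_k`` fits the scalar K to paired (c_B, c_PL, Hct) observations by
least squares on the plasma scale; the problem is one-dimensional, so a
bracketed bounded minimiser is used rather than a generic nonlinear solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import PairedMeasurement, Timepoint
from .errors import DomainError, EstimationError, InsufficientDataError

K_BOUNDS = (0.0, 50.0)
_XATOL = 1e-9


def plasma_from_blood(c_b, hct, k_bcpl):
    """Convert whole-blood concentration to plasma: c_b / ((1 - hct) + k * hct).

    Accepts scalars or numpy arrays. Raises :class:`DomainError` when the
    denominator is not positive (hct = 1 with k = 0).
    """
    c_b = np.asarray(c_b, dtype=float)
    hct = np.asarray(hct, dtype=float)
    if np.any(c_b < 0):
        raise DomainError("c_b must be >= 0")
    if k_bcpl < 0:
        raise DomainError("k_bcpl must be >= 0")
    denom = (1.0 - hct) + k_bcpl * hct
    if np.any(denom <= 0):
        raise DomainError(
            f"blood/plasma ratio (1-hct)+k*hct must be > 0, got {denom}"
        )
    out = c_b / denom
    return float(out) if out.ndim == 0 else out


def blood_from_plasma(c_pl, hct, k_bcpl):
    """Exact inverse of :func:`plasma_from_blood`: c_pl * ((1 - hct) + k * hct)."""
    c_pl = np.asarray(c_pl, dtype=float)
    hct = np.asarray(hct, dtype=float)
    if np.any(c_pl < 0):
        raise DomainError("c_pl must be >= 0")
    if k_bcpl < 0:
        raise DomainError("k_bcpl must be >= 0")
    out = c_pl * ((1.0 - hct) + k_bcpl * hct)
    return float(out) if out.ndim == 0 else out


@dataclass
class PartitionFit:
    """Result of fitting the partition coefficient K to paired data."""

    k_bcpl: float
    n: int
    sse: float
    ci_low: float
    ci_high: float
    se: float
    warnings: list[str] = field(default_factory=list)


def _sse(k: float, c_b: np.ndarray, c_pl: np.ndarray, hct: np.ndarray) -> float:
    pred = c_b / ((1.0 - hct) + k * hct)
    r = c_pl - pred
    return float(r @ r)


def _fit_k(c_b: np.ndarray, c_pl: np.ndarray, hct: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        _sse,
        bounds=K_BOUNDS,
        args=(c_b, c_pl, hct),
        method="bounded",
        options={"xatol": _XATOL, "maxiter": 500},
    )
    if not res.success:
        raise EstimationError(
            f"partition fit did not converge; last iterate k={res.x:.6g}"
        )
    return float(res.x)


def estimate_k(
    paired: Sequence[PairedMeasurement] | None = None,
    *,
    c_b=None,
    c_pl=None,
    hct=None,
    timepoint: Timepoint | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> PartitionFit:
    """Estimate the blood-cell-to-plasma partition coefficient from paired data.

    Either pass a collection of :class:`PairedMeasurement` (records lacking
    plasma or haematocrit are dropped; ``timepoint`` optionally restricts to
    trough or peak samples), or the three arrays directly.

    K minimises the sum of squared plasma-scale residuals
    ``sum (c_pl_i - c_b_i / ((1-hct_i) + K hct_i))^2`` over ``K in [0, 50]``.
    The 95 % confidence interval is a leave-one-out jackknife with a
    t(n-1) quantile; set ``n_bootstrap > 0`` (with ``seed``) to use a
    percentile bootstrap instead. All-identical haematocrit makes K
    unidentifiable alongside an overall scale; the fit is still returned but
    carries an identifiability warning.
    """
    if paired is not None:
        sel = [
            r
            for r in paired
            if r.complete and (timepoint is None or r.timepoint == timepoint)
        ]
        c_b = np.array([r.c_b for r in sel], dtype=float)
        c_pl = np.array([r.c_pl for r in sel], dtype=float)
        hct = np.array([r.hct for r in sel], dtype=float)
    else:
        c_b = np.asarray(c_b, dtype=float)
        c_pl = np.asarray(c_pl, dtype=float)
        hct = np.asarray(hct, dtype=float)

    n = c_b.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")

    warnings: list[str] = []
    if np.ptp(hct) == 0.0:
        warnings.append(
            "all haematocrit values identical: K is not identifiable "
            "separately from an overall blood/plasma scale"
        )

    k_hat = _fit_k(c_b, c_pl, hct)
    sse = _sse(k_hat, c_b, c_pl, hct)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boots[b] = _fit_k(c_b[idx], c_pl[idx], hct[idx])
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        se = float(np.std(boots, ddof=1))
    else:
        loo = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            loo[i] = _fit_k(c_b[mask], c_pl[mask], hct[mask])
            mask[i] = True
        se = math.sqrt((n - 1) / n * float(np.sum((loo - loo.mean()) ** 2)))
        tq = stats.t.ppf(0.975, n - 1)
        ci_low, ci_high = k_hat - tq * se, k_hat + tq * se

    ci_low = max(ci_low, 0.0)
    return PartitionFit(
        k_bcpl=k_hat,
        n=n,
        sse=sse,
        ci_low=float(min(ci_low, k_hat)),
        ci_high=float(max(ci_high, k_hat)),
        se=se,
        warnings=warnings,
    )
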