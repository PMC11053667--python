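"""Metabolite-to-parent ratio (MPR) screening.

The MPR — metabolite concentration divided by parent-drug concentration in the
same trough sample — is a proxy for metabolic clearance. Subjects whose MPR sits
outside the cohort's Tukey fences are candidates for enzyme induction (high
MPR) or inhibition / reduced-activity genotypes (low MPR); a Grubbs test on the
most extreme value quantifies the evidence. Because concentration ratios are
naturally log-distributed, the Grubbs statistic defaults to the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, DomainError, InsufficientDataError


def compute_mpr(parent, metabolite):
    """Metabolite/parent concentration ratio (dimensionless).

    Tables report it to three decimals; this function returns full precision.
    """
    parent = np.asarray(parent, dtype=float)
    metabolite = np.asarray(metabolite, dtype=float)
    if np.any(parent <= 0):
        raise DomainError("parent concentration must be > 0")
    if np.any(metabolite < 0):
        raise DomainError("metabolite concentration must be >= 0")
    out = metabolite / parent
    return float(out) if out.ndim == 0 else out


def tukey_hinges(values) -> tuple[float, float]:
    """Tukey's hinges: medians of the lower and upper halves, where for odd n
    the overall median belongs to both halves."""
    s = np.sort(np.asarray(values, dtype=float))
    n = s.size
    half = (n + 1) // 2
    return float(np.median(s[:half])), float(np.median(s[n - half:]))


@dataclass
class TukeyFences:
    fence_low: float
    fence_high: float
    q1: float
    q3: float
    flags: np.ndarray  # True where the value is outside the fences


def tukey_fences(values, k: float = 1.5) -> TukeyFences:
    """Flag values outside Q1 - k*IQR and Q3 + k*IQR (hinge-based quartiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(f"Tukey fences need n >= 4, got {v.size}")
    q1, q3 = tukey_hinges(v)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return TukeyFences(lo, hi, q1, q3, (v < lo) | (v > hi))


@dataclass
class GrubbsResult:
    g: float
    p_two_sided: float
    index: int  # position of the most extreme value
    scale: str  # "raw" or "log"


def grubbs_test(values, scale: str = "log") -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max |x_i - mean| / sd on the chosen scale, with
    p = min(1, 2n * P(T_{n-2} >= t)), t = sqrt(n(n-2)G^2 / ((n-1)^2 - nG^2)).
    G^2 >= (n-1)^2/n (the attainable maximum) yields p = 0.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise InsufficientDataError(f"Grubbs test needs n >= 3, got {n}")
    if scale == "log":
        if np.any(v <= 0):
            raise DomainError("log-scale Grubbs requires positive values")
        x = np.log(v)
    elif scale == "raw":
        x = v
    else:
        raise DomainError(f"unknown scale '{scale}'")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("zero standard deviation: Grubbs test degenerate")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    denom = (n - 1) ** 2 - n * g**2
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * g**2 / denom)
        p = min(1.0, float(2 * n * stats.t.sf(t, n - 2)))
    return GrubbsResult(g, p, idx, scale)


@dataclass
class MPRTable:
    """Per-subject MPRs with cohort summary, fences and outlier evidence."""

    per_subject: pd.DataFrame  # subject_id, dose, parent_conc, metabolite_conc, mpr, outlier
    mean: dict  # column -> cohort mean (dose, parent_conc, metabolite_conc, mpr)
    sd: dict
    q1: float
    q3: float
    fence_low: float
    fence_high: float
    grubbs_g: float
    grubbs_p: float
    grubbs_scale: str
    n: int

    @property
    def flagged_subjects(self) -> list[str]:
        return self.per_subject.loc[self.per_subject["outlier"], "subject_id"].tolist()


def summarize_cohort(
    table: pd.DataFrame, fence_k: float = 1.5, grubbs_scale: str = "log"
) -> MPRTable:
    """Build the cohort MPR summary from a trough table.

    ``table`` columns: subject_id, dose, parent_conc, metabolite_conc. Requires
    >= 2 subjects (>= 4 for fences) with positive parent concentrations and
    unique subject ids.
    """
    for col in ("subject_id", "dose", "parent_conc", "metabolite_conc"):
        if col not in table.columns:
            raise DomainError(f"trough table missing column '{col}'")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataValidationError(f"duplicate subject id '{dup}'")
    if len(table) < 2:
        raise InsufficientDataError("cohort summary needs >= 2 subjects")

    df = table.copy()
    df["mpr"] = compute_mpr(
        df["parent_conc"].to_numpy(), df["metabolite_conc"].to_numpy()
    )
    fences = tukey_fences(df["mpr"].to_numpy(), k=fence_k)
    df["outlier"] = fences.flags
    gr = grubbs_test(df["mpr"].to_numpy(), scale=grubbs_scale)

    cols = ["dose", "parent_conc", "metabolite_conc", "mpr"]
    return MPRTable(
        per_subject=df,
        mean={c: float(df[c].mean()) for c in cols},
        sd={c: float(df[c].std(ddof=1)) for c in cols},
        q1=fences.q1,
        q3=fences.q3,
        fence_low=fences.fence_low,
        fence_high=fences.fence_high,
        grubbs_g=gr.g,
        grubbs_p=gr.p_two_sided,
        grubbs_scale=gr.scale,
        n=len(df),
    )
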