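# Methods

## The partition model

A drug in whole blood is split between plasma (volume fraction `1 − Hct`) and
blood cells (`Hct`). Writing `K` for the blood-cell-to-plasma partition
coefficient (ratio of analyte concentration in cells to that in plasma), mass
balance over the two compartments gives

    c_B = c_PL · [(1 − Hct) + K·Hct]

which the package uses in both directions (`blood_from_plasma`,
`plasma_from_blood`). Two limits matter clinically: `K = 0`, the
plasma-confined case appropriate for glucuronide metabolites that need
transporters to enter cells, reduces to the haematocrit-only correction
`c_PL = c_B/(1 − Hct)`; and `K = 1` makes blood and plasma concentrations
equal regardless of Hct. The parent drug studied here has `K ≈ 1.57`
(lipophilic, accumulates in cells), so the haematocrit-only correction is
biased for it and the full relation is required.

**Estimation.** `estimate_k` minimises the plasma-scale sum of squares
`Σ (c_PL,i − c_B,i/((1−Hct_i)+K·Hct_i))²`. The problem is one-dimensional in
`K`, so a bounded bracketed scalar minimiser over `[0, 50]` with absolute
tolerance 1e-9 is used instead of a generic multivariate solver: it is
deterministic, derivative-free and cannot diverge. Residuals are defined on
the plasma scale because plasma is the clinical reference quantity. The 95 %
confidence interval is a leave-one-out jackknife (`SE² = (n−1)/n ·
Σ(θ̂₍ᵢ₎ − θ̄)²` with a `t(n−1)` quantile); a percentile bootstrap with an
explicit seed is available via `n_bootstrap`. If every subject has the same
haematocrit, `K` is confounded with an overall blood/plasma scale; the fit is
still returned but carries an identifiability warning. Peak and trough samples
are pooled by default (a `timepoint` filter is exposed) since the partition
equilibrium is not expected to depend on the sampling time.

## Method comparison

**Deming regression** allows measurement error in both the DBS and plasma
assays. With `λ` the ratio of y-error to x-error variance, the slope is the
closed-form root

    b = [S_yy − λS_xx + √((S_yy − λS_xx)² + 4λS_xy²)] / (2S_xy)

`λ = 1` by default: both assays show similar relative imprecision (~5 % CV),
and the comparison conclusions are insensitive to moderate changes in `λ`
(`λ → ∞` degenerates to ordinary least squares of y on x, which the tests
verify numerically). The **weighted** variant uses `w_i = 1/((x_i+y_i)/2)²`,
the standard choice when error is proportional to concentration; the weighted
moments feed the same closed form, iterated to a slope fixed point
(tolerance 1e-10 — for data-based weights this converges immediately; the
loop guards future weight schemes). Slope and intercept CIs are leave-one-out
jackknife with `t(n−1)`.

**Orientation.** The raw comparison regresses whole-blood concentration
(response) on measured plasma (comparator), so the slope is directly the
blood-to-plasma concentration ratio — `≈ mean(1−Hct)` for a plasma-confined
metabolite, `≈ mean((1−Hct)+K·Hct)` for the parent. The converted comparison
regresses partition-calculated plasma on measured plasma, where agreement
means slope ≈ 1, intercept ≈ 0.

**Bland–Altman** uses differences `a − b`, sample SD (n−1), limits of
agreement `mean ± 1.96·SD`, and a `t(n−1)` CI for the mean difference. A mean
difference whose CI covers zero indicates no systematic offset between the
converted DBS values and measured plasma.

## Assay validation

All statistics follow the bioanalytical-guideline conventions: bias% =
100·(mean found − nominal)/nominal; CV% uses the sample (n−1) SD. Calibration
is non-weighted ordinary least squares of the analyte/internal-standard
response ratio on nominal concentration at the assay's 11 levels
(0.1–20 µg/mL); non-weighted because that is the validated protocol for this
assay, with a `1/x²` option behind a flag for heteroscedastic use. At least 6
distinct levels are required (design error otherwise). Back-calculated
concentrations below the LLOQ are reported as-is and flagged, never clipped.
Inter-day precision pools all replicate values across days (15 = 5 × 3 by
default) rather than averaging day means, matching the convention of
reporting `n = 15`. Acceptance bands: ±15 % bias/CV (±20 % at the LLOQ,
which must also show a ≥ 5-fold signal over blank), matrix-lot slope
RSD < 4 %, stability within 100 ± 15 % of freshly prepared samples.

## MPR outlier screening

Quartiles for Tukey's fences are **hinges** (medians of the lower/upper
halves, with the overall median shared by both halves at odd n). On the
reference nine-patient cohort, hinges and linear-interpolation quartiles give
identical fences, so the convention choice does not affect the worked
example; it is documented because other cohorts can differ. Fences are
`Q1 − 1.5·IQR` and `Q3 + 1.5·IQR` (`fence_k` configurable).

The Grubbs test statistic is `G = max|x_i − x̄|/s` with the two-sided p-value
`p = min(1, 2n·P(T_{n−2} ≥ t))`, `t = √(n(n−2)G²/((n−1)²−nG²))`; `G²` at or
above its attainable maximum `(n−1)²/n` yields p = 0. The default scale is
**log**: concentration ratios are products of lognormal-ish quantities, so
normality — the Grubbs assumption — is more defensible on the log scale. A
raw-scale option is exposed, since the appropriate scale is a modelling
choice, not a fact about the data. On the reference cohort the log-scale
two-sided test gives p = 0.087 (≈ 0.09), the raw scale 0.29.

## Synthetic-data generator

The generator emulates a steady-state trough-monitoring study, not raw
chromatography:

- **Haematocrit**: normal(0.42, 0.05) truncated to [0.25, 0.55] — the adult
  clinical range.
- **Trough parent plasma concentration**: dose/clearance with doses from
  {100, 200, 250, 300, 400} mg/day, clearance lognormal (30 % CV, unit mean)
  around a scale chosen so an average 233 mg/day dose yields ~4.5 µg/mL,
  clipped to the 0.1–20 µg/mL analytical range. This one-compartment
  proportionality is all the MPR screen needs; no fuller pharmacokinetics is
  modelled.
- **Metabolite**: MPR lognormal with median location 0.32 and log-SD 0.45,
  times the parent concentration. `outlier_spec` multiplies chosen subjects'
  MPR by a clearance fold-change, emulating induction (> 1) or inhibition
  (< 1).
- **Partition**: blood concentrations derive from plasma with K = 1.57
  (parent) and K = 0 (metabolite).
- **Measurement error**: multiplicative unit-mean lognormal at 5 % CV,
  independent for blood and plasma — chosen because the validated assay shows
  near-constant CV% across its range. An additive noise floor is not
  modelled, so sub-LLOQ behaviour is idealised.
- **Calibration/QC runs**: responses linear in concentration at the 11 assay
  levels with per-lot slope variation at 2 % RSD (relative matrix effect) and
  the same multiplicative noise; QC found-values support injected per-level
  bias.

All draws flow from a single `numpy.random.Generator` seeded in the config.
What passing tests on this generator do **not** show: robustness to
chromatographic interferences, haematocrit-dependent spot spreading or
recovery, carryover/drift, non-lognormal error tails, or correlation between
a subject's two timepoints — real DBS data can exhibit all of these.

## Numerical choices and degenerate inputs

- Hct accepted as percent on input when in (1, 100] (divided by 100); exactly
  1.0 is taken as a fraction.
- CSV writing uses `%.17g` and reading uses round-trip float parsing so that
  write-then-read is an identity on every field.
- Deming with zero variance in both coordinates, or zero covariance, is a
  degenerate-data error, not a NaN.
- The jackknife CIs are clipped to contain the point estimate (relevant only
  when an estimate sits on the K ≥ 0 boundary).
- Sub-blank responses back-calculate to negative concentrations deliberately;
  flagging is the caller's decision.

## Problem sizes

The statistical guarantees are exercised at the study's own scales: the
nine-patient worked example exactly; coverage properties at 500 seeded
repetitions (200-pair cohorts for the partition CI, nine-subject cohorts for
the converted-agreement checks); the calibration linearity floor at 100
seeds. These sizes give Monte-Carlo standard errors comfortably below the
asserted margins while keeping the full suite fast.

## Known limitations

- Venous-blood spotting only is emulated; capillary (finger-prick) blood may
  partition differently.
- `K` is a scalar per analyte: no concentration dependence or saturable cell
  binding.
- Repeated measurements per subject (trough and peak) are pooled as
  independent in the comparison statistics; subject ids are retained so a
  clustered analysis could be added.
- No Passing–Bablok regression, total-error profiles, or incurred-sample
  reanalysis.
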