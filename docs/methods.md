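# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `qdce_pirads`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Pharmacokinetic core

**Arterial input function.** The plasma concentration C_p(t) is the Parker
population-averaged functional form: two Gaussians (first and second bolus
pass; amplitudes 0.809 and 0.330 mmol·min, centres 0.17046 and 0.365 min,
widths 0.0563 and 0.132 min) plus a sigmoid-gated exponential washout
(α = 1.050 mmol, β = 0.1685 min⁻¹, s = 38.078 min⁻¹, τ = 0.483 min). The
closed form does not vanish at t = 0 — the leading Gaussian contributes
≈ 0.06 mmol/L there, about 1% of the ≈ 6 mmol/L peak — and the late tail
follows α·e^(−βt), not a decay to zero; tests assert both structural facts.
Tiny negative values from floating-point evaluation are clipped to zero so
C_p ≥ 0 holds exactly. All ten parameters are a plain dataclass, so an
alternative population AIF is a one-line substitution.

**Tofts forward model.** C_t = K^trans · (C_p ⊛ e^(−k_ep t)) is evaluated by
trapezoidal quadrature of C_p(τ)e^(k_ep τ) on an internally refined grid
(10 sub-intervals per acquisition interval by default), then read out at the
acquisition times. Because 5–6 s sampling under-resolves the AIF first pass
(Gaussian width ≈ 3.4 s), refinement by linear interpolation of the sampled
AIF is not enough for absolute accuracy; when the AIF's functional form is
known it is passed as a callable (`aif_model`) and evaluated analytically on
the refined grid. With that, the 5 s-grid convolution agrees with a 0.1 s
direct evaluation to within 2% wherever the curve exceeds 1% of its peak
(tested). The quadrature is exact in the two analytic limits used as
oracles: K^trans = 0 (identically zero) and constant C_p (closed-form
saturating exponential, matched to 4 significant figures at 0.1 s sampling).
A guard rejects k_ep · duration > 500 where the exponential reweighting
would overflow.

**Inverse problem.** (K^trans, k_ep) are estimated by bounded
trust-region-reflective least squares (scipy `least_squares`), initialization
(0.1, 0.5) min⁻¹, bounds K^trans ∈ [0, 2], k_ep ∈ [0, 10] min⁻¹ — a
generous physiologic prostate range. Convergence is reported as a flag, never
an exception; an all-zero tissue curve lands on the K^trans = 0 boundary with
`at_boundary` set (boundary proximity judged at 10⁻⁶ of the box width).
Noiseless forward curves are recovered to 10⁻³ relative error across
K^trans ∈ [0.05, 0.35] × k_ep ∈ [0.3, 1.0] (tested on the 7×5 grid).

**ADC.** Monoexponential fit: ordinary least squares of ln(signal) on b,
negated slope reported in 10⁻⁶ mm²/s. ROI reduction exposes both mean
(primary) and median (robustness variant).

## Synthetic cohort generator

The generator's defaults encode the matched surgical cohort the package is
designed around; they are study conditions, not tuning knobs.

* **Covariates** (age, PSA, PV) are log-normal, pinned to the printed
  per-group medians and IQRs (e.g. AA PV median 41 cc, IQR 23). Log-normals
  were chosen because these are strictly positive, right-skewed clinical
  variables; σ is solved from IQR/median via asinh, so the configured median
  and IQR are exact distributional properties (tested at n = 10,000).
  PSA density is derived (PSA/PV), never sampled.
* **Lesion multiplicity** is 1 + Poisson(λ) with λ = mean − 1 per group
  (AA 1.7, W 1.5 lesions/patient): every prostatectomy patient carries at
  least one pathology lesion.
* **Grades and scores.** ISUP grades follow the per-group frequency tables;
  the printed "ISUP ≥ 4" (and "PI-RADS ≥ 4") rows are not broken down
  further, so they are split 70/30 into grade 4 vs 5 (score 4 vs 5). A
  pathology lesion is MRI-detected with a per-category probability
  calibrated from the printed TP/(TP+FN) counts — csPCa: 32/41 (AA), 64/83
  (W); ISUP 1: 4/22 and 10/28 (the difference between the all-lesion and
  csPCa detection counts). Detected lesions draw a PI-RADS score from the
  per-group frequencies; undetected ones are MRI-occult (PI-RADS 0).
  Pathology-negative MRI-only findings arrive as an independent Poisson
  stream at the printed FP-per-patient rates (8/37 and 9/74).
* **Quantitative MRI** values are normals truncated at zero with the
  published per-(group, stratum) mean ± SD — mean ± SD is what the source
  tables report and the quantities are non-negative. Strata: ISUP 1, ISUP ≥ 2
  (csPCa) and, for pathology-negative MRI-only findings, the PI-RADS ≥ 3
  MRI-based stratum. Truncation at zero raises the realized mean slightly
  (≈ +1.4% for the AA csPCa K^trans stratum, exact expression available as
  `TruncNormSpec.truncated_mean`); tests budget for this inside their
  tolerances. A known source discrepancy — the abstract's 0.23 ± 0.08 vs the
  table's 232.2 ± 102.4 (×10⁻³) SD for AA csPCa K^trans — is resolved in
  favour of the table; the abstract's values are one config line away.
* **Geometry.** The default sector map is a simplified 12-sector sheet
  (6 transition-zone + 6 peripheral-zone sectors); any richer zone-labelled
  map, up to a full PI-RADS v2.1 sheet, can be supplied. Each lesion sits in
  one zone (TZ with probability 0.30) and spans 1–4 sectors of that zone
  (frequencies 0.45/0.30/0.15/0.10). Zone assignment being exclusive means
  zonal cancer-prevalence shares sum to exactly 1; real lesions can straddle
  the TZ/PZ boundary (the labeling and statistics layers support
  cross-zone sector sets — only the generator does not produce them).
* **DCE curves** are the Tofts forward model driven by the analytic Parker
  AIF on the acquisition grid (default 5 s resolution, 5 baseline + 70
  post-injection frames), plus additive zero-mean Gaussian noise (pipeline
  default SD 0.02 mmol/L, a mild concentration-space noise level at which
  fitted K^trans track generative values with r > 0.95 in the pipeline
  test). Signal-to-concentration conversion is out of scope; curves live in
  concentration space.

Randomness: each config carries one integer seed; patients, lesions and
curves consume independent child streams (`default_rng([seed, k])`), so
every stage is individually reproducible and the whole pipeline is a pure
function of (config, seed).

**What passing tests do and do not show.** The generator reproduces the
summary statistics it is parameterized by (medians/IQRs, frequencies, rates,
stratum means) and the compositional structure of the analysis. It does not
model spatial correlation between lesions, within-patient correlation of
quantitative values, zone-dependent perfusion, grade-dependent lesion size,
or any MRI-visibility dependence of K^trans within a stratum — so results on
synthetic cohorts validate the machinery, not clinical effect sizes.

## Matching

Propensity = P(AA | age, PSA, PV) by maximum-likelihood logistic regression
(statsmodels). Greedy nearest-neighbour matching without replacement on the
logit scale, cases in descending propensity order, ties broken by patient id
(fully deterministic); caliper defaults to 0.2 × SD of the logit propensity,
the conventional width, since the source analysis does not state one. Cases
with fewer than `ratio` in-caliper controls are dropped and reported. Exact
reproduction of any particular historical cohort selection is not claimed.
A note on evaluating balance: the standardized mean difference of a matched
~100-case sample has sampling noise of order 0.1 itself, so balance checks
in the tests average over seeds rather than asserting per-seed bounds.

## Labeling, weighting and statistics

The TP/FP/FN truth table is taken literally from the criterion pair;
records negative on both modalities under a strict criterion become
EXCLUDED, carry zero weight, and never enter counts (the source analysis
drops them silently; here the category is explicit). Lesion-level
MRI↔pathology correspondence is an input — one record carries both findings
— because the original spatial matching was manual; this package reproduces
the analysis, not the annotation. Each counted lesion spreads weight 1/|S|
over its |S| sectors; whole-gland counts are therefore integers, zone counts
are weighted sums, and DR/PPV are invariant under any sector-map refinement
that splits sectors within a zone (tested).

Zonal cancer prevalence is defined as the zone's share of weighted
pathology-positive (TP+FN) mass — the source leaves the denominator
unspecified; this choice makes shares sum to 1 over zones when no sector
lies outside TZ/PZ. Undefined ratios (zero denominators) are reported as
missing, never 0.

The "weighted chi-square" is Pearson's X² computed on the 2×2 table of
weighted counts, df = 1, no continuity correction by default (flag
available); on integer tables it equals the classical statistic exactly, and
it scales linearly under a global reweighting — both verified against
independent oracles. The construction is a documented choice: the source
names the test but not its weighting. Mann-Whitney U uses the exact null for
combined n ≤ 20 without ties and the tie-corrected normal approximation
otherwise; an all-equal pooled sample returns p = 1 by convention.

## Threshold search

The update rule uses strict inequalities (upgrade when K^trans > T_high,
downgrade when K^trans < T_low), so boundary-equal values never re-score;
the downgrade target is fixed at PI-RADS 2 — both 1 and 2 are MRI-negative
under every supported criterion, so the choice cannot affect any count. The
default grid is 0–0.35 min⁻¹ in 0.001 steps (the resolution at which such
thresholds are conventionally reported), augmented with the no-op sentinel
(0, +∞) that guarantees feasibility, hence achieved DR ≥ baseline DR and
achieved PPV ≥ baseline PPV always. Because the rule splits into a
downgrade move depending only on T_low (PI-RADS ≥ 3 lesions) and an upgrade
move depending only on T_high (PI-RADS ≤ 2 lesions), every weighted count is
the sum of two one-dimensional profiles; the full DR/PPV surfaces over the
summed grid come from one vectorized pass, and the result is tested for exact
agreement with a nested-loop relabel-and-summarize oracle on coarse grids.
Ties among DR-maximizers break deterministically: highest PPV, fewest
re-scored lesions, smallest T_high, smallest T_low. The objective defaults
to whole-gland csPCa (ISUP ≥ 2, PI-RADS ≥ 3) and is configurable in scope
and criterion; zone-specific threshold pairs are out of scope.

A behavioural note: because the generator draws FN-lesion K^trans from the
same stratum distribution as detected lesions, synthetic cohorts often admit
aggressive upgrade thresholds (many FN→TP flips at little PPV cost), more so
than one would expect with real data where occult lesions tend to be less
perfused. The search contract (never worse than baseline; oracle-exact) is
what the tests assert.

## Pipeline

Stage order: simulate pool → match (1:2) → simulate/fit DCE for the matched
cohort → label → evaluate → tune → report. Lesion curves are fitted after
matching because only matched patients enter the analysis — mirroring the
motivating study's flow from a large initial pool to the analyzed cohort —
and downstream stages consume the *fitted* K^trans/k_ep, so measurement
error propagates realistically. Defaults: 37 AA cases against a 185-patient
W pool, noise SD 0.02 mmol/L, criteria (PI-RADS ≥ 3, ISUP ≥ 1) and
(PI-RADS ≥ 3, ISUP ≥ 2). Rounding to report precision happens only in
`report.md`; all CSVs and `metrics.json` keep full precision. The problem
sizes above were chosen so a complete run takes a few seconds on one core
while keeping per-group lesion counts near the motivating cohort's.

## Known limitations

* Standard Tofts only — no vascular term (v_p), no individual AIF
  estimation, no T1/B1 correction, no phantom-based error correction.
* Concentration-space curves only; DICOM/NIfTI and signal conversion are out
  of scope.
* Per-lesion analysis throughout; per-patient summaries and DR/PPV
  confidence intervals are not provided.
* Greedy matching is not optimal matching; with a hostile pool it can drop
  cases an optimal algorithm would keep.
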