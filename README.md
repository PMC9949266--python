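# qdce-pirads

Quantitative dynamic contrast-enhanced MRI (qDCE) pharmacokinetics and
K<sup>trans</sup>-augmented PI-RADS scoring for two-group prostate mpMRI
cohort analyses — with a fully seeded synthetic-cohort generator, so the
entire analysis is runnable and testable without patient data.

## The scientific problem

Prostate mpMRI is read with PI-RADS (a 1–5 suspicion score), but its
diagnostic performance can differ between patient groups — in particular
between African American (AA) and White (W) men — in ways not explained by
age, PSA, or prostate volume (PV). This package implements the quantitative
machinery needed to study that question against whole-mount histopathology
(WMHP) truth:

1. **qDCE quantitation.** Tissue gadolinium concentration follows the
   standard Tofts model,

   C<sub>t</sub>(t) = K<sup>trans</sup> ∫₀ᵗ C<sub>p</sub>(τ) e^(−k<sub>ep</sub>(t−τ)) dτ,

   where K<sup>trans</sup> (min⁻¹) is the volume transfer (wash-in) constant
   and k<sub>ep</sub> (min⁻¹) the efflux (wash-out) rate. The plasma input
   C<sub>p</sub>(t) is the population-averaged Parker arterial input function
   (two Gaussian bolus passes plus a sigmoid-gated exponential washout).
   Parameters are estimated by bounded nonlinear least squares; ADC is fitted
   by ordinary least squares of log-signal over b-values (0/100/400/800 s/mm²).
2. **Cohort construction.** AA cases are matched 1:2 to W controls by greedy
   propensity-score caliper matching (logistic model on age, PSA, PV; caliper
   0.2 × SD of the logit propensity).
3. **Radiology–pathology statistics.** Each lesion is labeled TP/FP/FN under
   a configurable criterion pair (MRI-positive: PI-RADS ≥ 3 or 4;
   pathology-positive: ISUP ≥ 1 or 2). Lesions distribute unit weight evenly
   over the prostate sectors they occupy, giving zone-stratified weighted
   counts and the derived detection rate DR = TP/(TP+FN), positive predictive
   value PPV = TP/(TP+FP), and zonal cancer prevalence. Groups are compared
   with a weighted Pearson chi-square (categorical) and Mann-Whitney U
   (continuous).
4. **K<sup>trans</sup>-augmented PI-RADS.** PI-RADS 1–2 (or occult) lesions
   are upgraded to 3 when K<sup>trans</sup> > T_high; PI-RADS 3–5 lesions are
   downgraded to 2 when K<sup>trans</sup> < T_low. The (T_low, T_high) pair is
   tuned per group by exhaustive grid search (0–0.35 min⁻¹) maximizing DR
   subject to PPV not dropping below baseline.

The synthetic generator emulates the matched-cohort structure of a published
surgical cohort (37 AA : 74 W patients, ~1.6 pathology lesions/patient,
published ISUP/PI-RADS frequencies and per-group quantitative-MRI strata) and
simulates DCE curves at 5 s resolution with 5 baseline + 70 post-injection
frames. See `docs/methods.md` for the generative model and its limitations.

## Worked example

```bash
qdce-pirads run --outdir demo --seed 7
```

prints

```
report written to demo/report.md
AA: t_low=0.000 t_high=0.319 DR 81.8% -> 84.1%
W: t_low=0.027 t_high=inf DR 84.4% -> 84.4%
```

i.e. for the AA sub-cohort the search found that upgrading MRI-negative
lesions with K<sup>trans</sup> > 0.319 min⁻¹ raises csPCa detection from
81.8% to 84.1% at no PPV cost, while for W men only a small downgrade
threshold was admissible. `demo/report.md` contains the full tables; e.g.
the covariate balance table shows matching at work (PV standardized mean
difference 0.14 pre → −0.011 post, Mann-Whitney p 0.42 → 0.86), and the
quantitative summary for csPCa lesions reads

```
Ktrans csPCa: AA 0.244+-0.106 (n=44)  W 0.208+-0.071 (n=77)  p=0.045
```

— the AA stratum is generated (and recovered through curve fitting) with
higher perfusion, and the group difference is detected by the Mann-Whitney
comparison. Every stage can also be run individually
(`simulate | match | fit | label | evaluate | tune-thresholds | report`),
all consuming/producing documented CSVs in `--outdir`.

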