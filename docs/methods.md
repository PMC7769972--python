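# Methods

## The measurement model

A subject contributes one axial CT slice at the level of the superior
mesenteric artery and a binary mask of the bilateral paraspinal compartment
(the region bounded by the thoracolumbar fascia). All downstream quantities
are functions of the in-mask HU histogram and the pixel geometry:

| quantity | definition | units |
|---|---|---|
| compartment area | all mask pixels × pixel area | cm² |
| muscle area | pixels with −29 ≤ HU ≤ 100 | cm² |
| fatty area | pixels with −29 ≤ HU ≤ 29 | cm² |
| lean area | pixels with 30 ≤ HU ≤ 100 | cm² |
| FMF | 100 · fatty / (fatty + lean) | % |
| mean attenuation | mean unrounded HU over muscle pixels | HU |
| SMI | muscle area / height² | cm²/m² |

**Rounding rule.** The thresholds are integers, which leaves real-valued HU
in the open interval (29, 30) unassigned. Pixels are rounded to the nearest
integer, halves away from zero, before classification: 29.4 is fatty, 29.6
is lean, −29.5 falls below the muscle window. Mean attenuation is computed
on unrounded values — it is a mean, not a class. An alternative reading
(mean over the whole compartment rather than the muscle window) exists in
the wider literature; this package fixes the muscle-window definition and
exposes no flag for the alternative, since every derived statistic here
uses the muscle-window mean.

**Calibration is mandatory.** Areas are silently wrong if spacing is
guessed and classes are wrong if stored values are not rescaled, so the
loaders refuse DICOMs without `PixelSpacing` or `RescaleSlope/Intercept`
and NIfTIs with non-positive `pixdim`, instead of defaulting to 1 mm.
Masks are "any nonzero value is inside"; no multi-label support. The
dichotomisation is strict: FMF > cutoff is "high", ties go to "low"; the
automatic cutoff is the sample median (mean-of-middle-two convention).

## Phantoms

A phantom is a 128×128 grid at 1.0 mm spacing: two 30×20 mm elliptical
compartments flanking a 15 mm "vertebra" disc at 700 HU on a −100 HU
(fat-like) background. Given a target FMF f, the compartment's N pixels are
assigned labels by **exact counts** — round(bone_fraction·N) bone, then
round(f/100 · N_soft) fatty, the rest lean — rather than per-pixel
Bernoulli draws, so the ground truth is sharp up to integer rounding. HU
values are drawn per label from truncated normals (defaults: fatty
5 ± 12 HU, lean 45 ± 12 HU) whose supports, [−29, 29.49] and
[29.5, 100.49], map into the correct class after rounding; the measurement
therefore recovers the true FMF *exactly*, which is what the closed-loop
tests assert. With `truncate=False` the normals are unbounded and pixels
can cross the 29/30 boundary; recovery is then only approximate (observed
error ≲ 0.3 FMF points at sd 5 HU, asserted ≤ 2). A truncation interval
narrower than the requested sd is rejected as infeasible.

Phantoms deliberately omit CT physics — no beam hardening, partial volume,
reconstruction kernel or noise correlation — so closed-loop exactness
demonstrates correctness of the counting pipeline, not robustness to
scanner effects.

## Cohort simulator

Defaults emulate the published cohort of 87 adults on venovenous ECMO for
acute respiratory failure:

| field | family | calibration |
|---|---|---|
| age | Normal(54, 13) truncated to [18, 90] | cohort mean ± SD |
| sex | Bernoulli, P(male) = 58/87 | cohort count |
| BMI | log-normal, median 28.6, IQR ≈ (24.7, 34.7) | cohort median/IQR |
| FMF | logit-normal on [0, 100] | median ≈ 44, IQR ≈ (29, 65) |
| muscle area | Normal(44.1, 11.8) truncated > 0 | cohort mean ± SD |
| SMI | Normal(25.2, 6.1) truncated > 0 | cohort mean ± SD |
| mean attenuation | 45 − 35·FMF/100 + N(0, 4), clipped | overall mean ≈ 26.9 HU at median FMF |
| CCI | rounded Gamma | median 2, IQR (1, 3) |
| SAPS II | Normal(45.2, 12.9) | cohort mean ± SD |
| RESP score | logit-normal | median 45, IQR (39, 65) |
| ECMO days | log-normal | median 11, IQR (7, 17) |
| renal failure / weaning | Bernoulli 36/87, 50/87 | cohort counts |

The FMF and RESP logit-normals are fitted by a small two-parameter least
squares on the three quantiles (median weighted double); three constraints
on two parameters cannot all be met exactly, and the fit lands the large-n
sample median within ~1.5 points of 44. Covariates are drawn independently
— the study reported no correlation between FMF and the clinical model
covariates — with SMI drawn marginally rather than derived from a simulated
height, because the published muscle area (44.1 cm²) and SMI (25.2 cm²/m²)
jointly imply implausible heights (~1.32 m); drawing both marginals keeps
each printed summary faithful.

**Survival.** T ~ Weibull(shape k, default k = 1 i.e. exponential) with
hazard rate = baseline_rate · exp(Σ βⱼxⱼ), administratively censored at 365
days (the study analyses one-year mortality and reports no loss to follow
up). The default coefficient vector is βFMF = ln(1.017) per percent —
the published adjusted hazard ratio — and zero elsewhere. When
`baseline_rate` is unset it is calibrated by bisection so the *marginal*
one-year survival, averaged over a fixed-seed 20 000-subject covariate
sample, equals 36%; the calibration is deterministic and independent of the
cohort seed. All randomness flows from `numpy.random.default_rng` seeded by
the config, with separate streams for covariates and event times.

## Statistical procedures

* **χ² (2×2)**: n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], no continuity
  correction — validated against the published statistics 3.886 and 5.259
  recomputed from the printed counts. p from χ²(1).
* **Fisher's exact**: two-sided, sum of hypergeometric probabilities of
  tables no more probable than the observed (scipy); tests cross-check a
  full enumeration oracle.
* **t-test**: pooled-variance Student t with df = n₁+n₂−2, reported
  unsigned (Welch would not reproduce the published t = 0.630 from the
  printed summaries). A summary-statistics entry point accepts printed
  mean/SD/n triples directly.
* **Mann–Whitney U**: midrank ties, U = min(U₁, U₂). Exact p by complete
  enumeration of the C(n, n₁) group assignments when n₁+n₂ ≤ 12 (p = share
  of assignments with min-U ≤ observed); otherwise the tie-corrected normal
  approximation without continuity correction, which returns p = 1 exactly
  for identical samples.
* **Shapiro–Wilk**: delegated to scipy's Royston implementation; the
  package surface exists so the table-one normality gate (both groups must
  pass at α = 0.05 for a t-test, else Mann–Whitney) is explicit and
  testable.
* **Kaplan–Meier / log-rank**: product-limit estimator over death times;
  log-rank as Σ(O−E) with hypergeometric variance, df = 1. With no
  censoring KM equals the empirical survival exactly, and the log-rank
  statistic equals the Cox score test at β = 0 on a group indicator
  (asserted to 1e-8); both are also cross-checked against lifelines.
* **Cox PH**: Newton–Raphson on the partial likelihood, Breslow tie
  handling by default (Efron behind a flag), convergence at 1e-8 maximum
  coefficient change, cap 100 iterations with step-halving to force
  likelihood ascent; non-convergence sets a flag rather than failing
  silently. Wald CIs exp(β ± 1.96·SE) and Wald p-values (the published
  table does not state Wald vs likelihood-ratio; Wald is the implemented
  reading). Sex is coded female = 1, male = 0; booleans 0/1; complete cases
  required, constant covariates rejected. The Breslow derivative
  computation is vectorised with cumulative risk-set sums over
  descending-time order, so an 8-covariate fit of 8700 subjects takes
  ~0.2 s.
* No multiple-testing correction anywhere, mirroring the analysis being
  reproduced; every p is raw.

The model the analysis names is worth a note: the source describes a
"multivariable logistic regression" yet reports hazard ratios from a Cox
regression alongside Kaplan–Meier curves. Only the proportional-hazards
reading is consistent with per-unit hazard ratios and censored follow-up,
so this package implements Cox; no logistic fallback is provided.

## Problem sizes and verification

The recovery study simulates 50 cohorts of n = 8700 (100× the study) at
βFMF = ln(1.017): every fit is expected inside HR ∈ [1.012, 1.022] at this
n (observed median ≈ 1.0169). Null calibration uses 200 cohorts of n = 870
with all β = 0 and checks that the 95% Wald CI for the FMF hazard ratio
covers 1.0 about 95% of the time (a 200-replicate estimate carries ±1.5
points of binomial noise). The phantom closed loop sweeps true FMF over
{0, 10, …, 100}. These sizes were chosen to make the Monte-Carlo noise
small relative to the bands being asserted while keeping the whole suite
interactive (~15 s).

## Known limitations

* Single-slice, stored-orientation workflow: no volumetric segmentation,
  landmark detection, reorientation or registration.
* Phantoms and simulated cohorts validate the computational pipeline, not
  clinical transportability: passing tests say nothing about scanner
  protocol effects, contrast phase, or cohorts unlike the calibration one.
* The simulator's covariate independence is a modelling default taken from
  the reported absence of correlation; real ICU covariates are correlated.
* RESP score is treated as a continuous percentage (as the analysis used
  it), not reconstructed from its categorical scoring rules; CCI and
  SAPS II are likewise inputs, never computed.
* Missing covariates are an error (complete cases); how the original fit
  handled its internally inconsistent renal-failure denominators is
  unknown, and that statistic is not reproduced.
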