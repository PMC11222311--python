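# Methods

This note documents the models, defaults and numerical choices behind
`glycotraj`, and what the synthetic cohorts do and do not establish.

## Cohort rules

Diabetes is identified by diagnosis-code prefixes (ICD-9 `250`; ICD-10
`E10`–`E14`) and CABG by procedure-code prefixes (ICD-9 `3611`–`3619` and
`362`; ICD-10-PCS `0210`–`0213`); matching is case-insensitive with dots
stripped, and `362` is treated as a prefix (covering `3621`, `3622`, …)
since it is listed alongside prefix ranges. Exclusions fire in a fixed
order — age < 18; ICU stay < 24 h; coma/delirium within 24 h; dementia,
psychoses, traumatic brain injury, reading disorder, intellectual
disability or neurological disease; alcohol/drug abuse; non-first
admission — and a record failing several rules is logged once under the
first. "Coma or delirium within 24 h" is consumed as a precomputed flag:
how repeated assessments collapse into it (any vs. all) is a charting
question the caller must answer; `adjudicate_assessments` offers an
any-positive convention. Delirium adjudication: RASS < −3 is coma
(ineligible; −3 exactly remains eligible); otherwise delirium requires
CAM-ICU features 1 and 2 plus 3 or 4.

## Glycemic indices

Unit conversion uses 18.016 mg/dL per mmol/L (glucose molar mass
180.16 g/mol). Time differences use the actual charted times, not an
assumed 4-h spacing; on the canonical grid ΣΔt = 20 h. Readings are sorted
by time defensively, then required strictly increasing.

MAGE needed several decisions its one-line textbook definition leaves
open: the threshold SD is the sample (n−1) standard deviation of all
readings; plateaus collapse to a single extremum at their first index; an
excursion requires at least one interior turning point, so monotone or
constant series score 0 rather than missing (keeping six-point series
comparable); endpoints then serve as terminal extrema; qualifying
excursions are those strictly greater than 1 SD, and their mean is
reported, or 0 when none qualifies. These choices preserve the invariant
MAGE ≤ LAGE (in common units) on every series. MAGE needs ≥ 3 readings;
all other indices need ≥ 2; a per-patient completeness flag is emitted.

Strata: hyperglycemia boundaries are `[140, 200)` mg/dL (200 is severe);
variability indices are high iff *strictly greater* than the cutoff.
Fixed-mode cutoffs are the published cohort medians (MAG 0.77 mmol/L/h,
MAGE 2.58 mmol/L, GLI 2.6 (mmol/L)²/h, LAGE 79.2 mg/dL); median mode
recomputes them from the supplied cohort. GLI's printed unit in the source
literature ("(mmol/L)²/h/per se") is internally inconsistent; the formula
Σ Δg²/Δt in (mmol/L)²/h is implemented.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
a categorical trajectory class per patient; within class k, glucose(t) =
β₀ₖ + β₁ₖt + β₂ₖt² + bᵢ + ε with a patient random intercept and
residual noise, floored at 40 mg/dL (physiological floor, keeps indices
finite); covariates from independent marginals matching the reference
cohort's medians, IQR-implied spreads and category shares (e.g. age
median 68, eGFR 83, 74% male); and a Bernoulli delirium outcome whose
logistic linear predictor combines the realized index strata, the true
class, and a parsimonious covariate set, with effect sizes defaulting to
the reference cohort's fully adjusted odds ratios. The intercept is
calibrated by bisection of the expected prevalence (smooth and strictly
increasing in the intercept) to the reference 180/1951 ≈ 9.23%.

Defaults that the source analysis does not pin down, chosen once:

- **Curve coefficients.** No numeric trajectory coefficients are published
  for the four classes — only shapes and proportions
  (87.7/6.46/1.33/4.51%). The defaults (160, −2, 0.04), (220, −9, 0.38),
  (330, −20, 0.8), (185, 6, −0.35) reproduce those shapes (low steady
  decline; decline-then-rise; high-start decline-then-rise; mild
  rise-then-decline) on a realistic mg/dL scale. Together with
  σ_b = 15 mg/dL and σ = 20 mg/dL they give the emulated cohort the class
  sharpness the reference analysis demonstrably had — its selection
  protocol succeeded with entropy > 0.7 and mean posteriors > 70% — which
  a blurrier cohort would not reproduce.
- **Random effects.** Random intercept only (no random slope): the
  smallest structure separating within- from between-patient variance;
  configurable.
- **Variability-index dichotomies.** MAG/MAGE/GLI/LAGE are split at the
  *simulated cohort's own medians*, mirroring how the reference cutoffs
  were defined. The published absolute cutoffs cannot be used here: under
  i.i.d. Gaussian reading noise no noise level jointly matches the
  published MAG and GLI medians (they are mutually inconsistent for any
  σ), so absolute cutoffs would produce a degenerate, nearly-constant
  exposure. The pipeline's `threshold_mode` defaults to `median` for the
  same reason; `fixed` retains the published cutoffs for work on real
  data.
- **Outcome coefficients.** MAG is the single variability-index effect in
  the default linear predictor; GLI/LAGE associations then emerge through
  correlation rather than double-counting near-collinear indices. Baseline
  glucose is the T1 reading.

What the generator does **not** emulate: inter-covariate correlation
structure (covariates are independent draws), informative missingness,
measurement rounding, within-day circadian structure, or any relationship
between covariates and the glucose curves. Passing tests therefore show
that the estimators recover what this generative model plants — not that
the clinical findings replicate on real ICU data.

## Trajectory mixture (EM)

Both the class label and the random intercept are latent. The E-step
evaluates each patient's marginal multivariate-normal density per class
(covariance σ_b²J + σ²I on the patient's grid, inverted analytically) and
the conditional mean/variance of bᵢ; the M-step updates mixing
proportions, class curves by responsibility-weighted least squares on the
intercept-corrected readings, and both variance components in closed
form. This is an exact EM, so the observed-data log-likelihood is
non-decreasing; the fitter asserts it each iteration.

Numerics: time is centered at 12 h and scaled by 12 for conditioning, and
coefficients (with delta-mapped Wald SEs from the weighted GLS
information) are reported on the hour scale. Initialization clusters
per-patient OLS quadratic coefficients by k-means; further restarts use
random responsibilities; the best final log-likelihood wins, and a restart
that collapses a class (π < 10⁻⁶) is redrawn and counted. Convergence is
a relative log-likelihood change < 10⁻⁶, capped at 1000 iterations
(σ_b² → 0 boundary cases converge slowly). Patients are grouped by
identical time grids so the E/M steps run vectorized. Free parameters:
p = 3K + (K−1) + 2.

Class selection keeps candidates with entropy > 0.7 (relative entropy
1 − Σ(−p log p)/(N log K); defined as 1 for K = 1), every MAP class share
≥ 1%, and every class's mean MAP-member posterior > 70%, then takes the
smallest BIC (ties: smaller AIC, then larger K). The "largest
log-likelihood ratio" condition is monotone-equivalent to the information
criteria across K and is subsumed by them. Classes are reported in
descending mixing-proportion order; posterior ties in MAP assignment
break toward the lower class index. K = 1 is cross-checked in the tests
against direct mixed-model ML (statsmodels MixedLM) to 10⁻⁴
log-likelihood units.

## Association models

Logistic models are maximum likelihood via IRLS (statsmodels GLM,
binomial family), deviance tolerance 10⁻⁸, 100 iterations. Odds-ratio CIs
are Wald, exp(β̂ ± 1.96·SE) — on 2×2 tables this reproduces the reference
tables' printed CI arithmetic exactly, which profile-likelihood intervals
would not. Pearson χ² carries no continuity correction (again matching
the printed statistics; Yates-corrected values would not match). The
Mann–Whitney test is reported as a tie-corrected, continuity-corrected
normal-approximation Z, signed so that an event group with larger values
gives negative Z. Separation is flagged when any slope magnitude exceeds
15 (the intercept is exempt: it legitimately grows with unscaled
covariate means) or the outcome is constant; rank-deficient designs are
rejected naming the collinear columns. Missing data are handled
complete-case per model with per-model n reported.

The five adjustment sets are nested: none; {age, HR, SpO₂}; + {RDW,
hematocrit, eGFR, INR, PT, BUN, bicarbonate, Na}; + {SOFA, CCI};
+ {sepsis, CKD, mechanical ventilation, vasopressor}. Exposures are
dummy-coded against their declared references (no hyperglycemia; ≤ median;
class 1). Subgroups (age 65, gender, race, eGFR 60, INR 1.5, sepsis,
ventilation, vasopressor) use the full adjustment set minus the
stratifying variable; a stratum whose fit is impossible (zero events,
separation) is flagged inestimable rather than raised. Univariate
screening retains candidates with p < 0.05, no multiplicity adjustment.

## Additive interaction

Joint exposure coding uses the doubly-unexposed reference (low glycemic
index and low INR / preserved eGFR); "low" is ≤ the cutoff, and for eGFR
the *low* side is the exposed one. Default cutpoints: MAG 0.77, GLI 2.6,
MBG 140 mg/dL (the hyperglycemia boundary; the source tables say only
"High MBG"), INR 1.5, eGFR 60 — all configurable, with a median mode for
simulated cohorts. RERI and AP CIs use the delta method on the three
joint log-odds with the fitted covariance (the Hosmer–Lemeshow
construction), the default because the source names no method; a
patient-level nonparametric bootstrap with percentile intervals is
offered, re-dichotomizing within each resample. Adjusted models use the
full covariate set minus the modifier itself. A joint cell with zero
events raises (single-pair API) or is flagged inestimable (table API).

## Problem sizes and calibration checks

The test-suite and acceptance-script simulations are sized for precise
yet quick checks, chosen as follows: class-share and prevalence
calibration at n = 20,000 (3-binomial-SE bands); 2-class parameter
recovery at n = 500; the class-selection protocol at n = 2,000 in the
deterministic test and n = 5,000 in the seed-driven acceptance script —
the smallest class is 1.33% of the cohort, and at n = 2,000 its sampled
share falls below the 1% gate for an appreciable fraction of seeds, which
reflects binomial sampling, not the fitter; delta-method CI coverage over
500 replicates of n = 5,000 (±3 SEs of 95%).

## Known limitations

- The growth mixture assumes a shared residual variance and a shared
  random-intercept variance across classes, no covariates in the
  class-membership model, and no Bayesian estimation.
- Reference adjusted results (Models 2–5, subgroup ORs, RERI/AP on real
  data) depend on the access-restricted clinical database and are not
  reproducible here; only count-derivable statistics are checked exactly.
- MAGE is specified for sparse (6-point) series; continuous-monitoring
  variants (and CONGA/MODD/ADRR) are out of scope.
- The exclusion filter trusts supplied flags and `icu_los_hours`; it does
  no date arithmetic or chart-event inference.

## Data dictionary (CSV interfaces)

Long glucose table: `patient_id`, `time_h` (hours since ICU admission),
`glucose_mgdl`. Records table: `patient_id`, `admission_index` (1 =
first), `age`, `icu_los_hours`, exclusion flags (`coma_or_delirium_24h`,
`dementia`, `psychoses`, `tbi`, `reading_disorder`,
`intellectual_disability`, `neurological_disease`,
`alcohol_drug_abuse`), covariates (`gender`, `race`, `insurance`, `hr`,
`dbp`, `sbp`, `temperature`, `spo2`, `ph`, `wbc`, `rdw`, `platelet`,
`hematocrit`, `egfr`, `inr`, `pt`, `bun`, `bicarbonate`, `na`, `k`,
`chloride`, `sofa`, `cci`, `gcs`, and binary `sepsis`, `cvd`, `ckd`,
`liver_disease`, `depression`, `mech_vent`, `vasopressor`, `sedative`,
`antibiotic`), outcome `pod` ∈ {0, 1}. Assessments table (long):
`patient_id`, `rass`, `feature1`–`feature4`. Diagnosis/procedure code
lists, where used, are semicolon-delimited `code:version` strings.
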