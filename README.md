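# glycotraj

Glycemic variability, 24-h glucose trajectory classes, and
postoperative-delirium association analysis for ICU cohorts.

After coronary artery bypass grafting (CABG), diabetic patients face a
substantial risk of postoperative delirium (POD), and how the blood-glucose
profile over the first 24 ICU hours relates to that risk is contested. This
package implements, as a tested and reusable pipeline, the full analysis
used to study that question in a MIMIC-IV-derived cohort of 1,951 diabetic
CABG patients (180 POD cases): glycemic-index computation, latent-growth-
mixture trajectory classification, nested logistic-regression association
models, subgroup analyses, and additive-interaction statistics — together
with a synthetic-cohort generator so every stage is testable without access
to restricted clinical data. It is aimed at biostatisticians and
epidemiologists reanalyzing ICU glucose data or auditing this class of
analysis.

## What it computes

**Glycemic indices** from a patient's readings g(t₁) … g(t₆) (mg/dL, 4-h
grid over 24 h):

- MBG = mean g; LAGE = max g − min g
- MAG = Σᵢ|Δgᵢ| / ΣᵢΔtᵢ (mmol/L/h), GLI = Σᵢ Δgᵢ²/Δtᵢ ((mmol/L)²/h)
- MAGE = mean of adjacent peak–valley amplitudes exceeding 1 SD of the
  series (mmol/L)

with the standard strata: hyperglycemia <140 / [140, 200) / ≥200 mg/dL for
baseline and MBG, and median dichotomies for the variability indices.

**Trajectory classes** via a latent growth mixture model fitted by EM: in
class k, yᵢₜ = β₀ₖ + β₁ₖt + β₂ₖt² + bᵢ + εᵢₜ with bᵢ ~ N(0, σ_b²),
ε ~ N(0, σ²). Class number K is chosen by the four-condition protocol:
smallest BIC/AIC and largest log-likelihood among candidates with relative
entropy > 0.7, every class ≥ 1% of the cohort, and mean posterior
probability > 70% per class.

**Associations** as odds ratios with Wald 95% CIs, exp(β̂ ± 1.96·SE), from
maximum-likelihood logistic regression, across five nested adjustment
models (unadjusted → demographics/vitals → labs → severity scores →
comorbidities/treatments), plus Mann–Whitney/χ² descriptive tables,
univariate covariate screening and per-stratum subgroup models.

**Additive interaction** between a dichotomized glycemic exposure E and a
hepatorenal modifier M (INR ≥ 1.5; eGFR < 60):
RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 and AP = RERI/OR₁₁, with delta-method or
bootstrap CIs; a CI excluding 0 flags a super-additive (synergistic)
effect.

## Worked example

```python
from glycotraj import GlucoseSeries, compute_indices, stratify_indexes

series = GlucoseSeries("demo-001", times=[0, 4, 8, 12, 16, 20],
                       values_mgdl=[196, 148, 122, 165, 141, 118])
ix = compute_indices(series)
stratify_indexes(ix)
```

prints (see `examples/01_glycemic_indices.py`):

```
baseline glucose :  196.00 mg/dL (mild hyperglycemia)
MBG              :  148.33 mg/dL (mild hyperglycemia)
LAGE (max - min) :   78.00 mg/dL  high=False
MAG              :   0.455 mmol/L/h  high=False
MAGE             :   3.034 mmol/L  high=True
GLI              :   4.571 (mmol/L)^2/h  high=True
```

This patient's average level is only mildly elevated, but the swings are
large (MAGE and GLI above the published cohort medians) — exactly the
dissociation between level and lability the indices are designed to
expose. Running the trajectory stage on a simulated default cohort
(`examples/03_trajectory_classes.py`) selects K = 4 classes with entropy
0.90 and recovers the four generating shapes (a dominant low-declining
class of ~86%, a decline-then-rise class, a rare very-high-glucose class
and a rise-then-decline class); the interaction stage
(`examples/05_interaction_reri.py`) reports, on an 8,000-patient simulated
cohort, RERI = 0.641 (95% CI 0.148–1.133) for MAG × INR — a significant
super-additive effect, the expected signature of a generating model that is
multiplicative on the odds scale.

The `examples/` directory holds one short script per capability; the
`glycotraj` command-line tool (`glycotraj simulate|cohort|indices|
trajectory|associate|interact|run`) wraps the same functions for
file-to-file use.

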