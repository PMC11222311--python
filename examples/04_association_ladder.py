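"""Nested logistic-regression ladder relating a glycemic exposure to
postoperative delirium.

Model 1 is unadjusted; Models 2-5 add demographics/vitals, labs, severity
scores, and comorbidities/treatments. The published unadjusted MAG odds
ratio (2.388, CI 1.719-3.319) is also recomputed from the reference
cohort's printed contingency counts.
"""

from glycotraj import SimulationConfig, generate_cohort, or_from_counts, \
    run_model_ladder
from glycotraj.datasets import CONTINGENCY_COUNTS

levels, ref, counts = CONTINGENCY_COUNTS["mag"]
row = or_from_counts(counts, levels, ref).loc["high"]
print("reference cohort, unadjusted MAG>median OR: "
      f"{row['or']:.3f} (95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f})")

cohort = generate_cohort(SimulationConfig(n_patients=1951))
records = cohort.records.merge(
    cohort.true_classes.rename("trajectory_class"), on="patient_id")
ladder = run_model_ladder(records, "mag_high")
print("\nsynthetic cohort, MAG>median OR per adjustment model:")
for _, r in ladder.iterrows():
    print(f"  model {int(r['model'])}: OR {r['or']:.3f} "
          f"({r['ci_low']:.3f}-{r['ci_high']:.3f}), p={r['p']:.4f}")
print("\nThe adjusted ORs stay close to the unadjusted one: the generator "
      "draws glucose noise independently of the covariates, so there is "
      "little confounding for the ladder to remove.")
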