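"""Run the whole pipeline end to end on a simulated cohort.

simulate -> cohort exclusions -> glycemic indices -> trajectory classes ->
association models -> additive interaction, writing CSV/JSON outputs and a
run manifest under ./scratch/pipeline_demo.
"""

import json

from glycotraj import RunConfig, run_pipeline

config = RunConfig(out_dir="scratch/pipeline_demo", seed=7, n_patients=800,
                   kmax=3, n_restarts=2, models=(1, 5),
                   exposures=("mbg_stratum", "mag_high", "gli_high"),
                   subgroups=("gender", "age"), pairs=(("mag", "inr"),))
manifest = run_pipeline(config)

for stage in manifest["stages"]:
    extra = {k: v for k, v in stage.items() if k not in ("stage", "elapsed_s")}
    print(f"{stage['stage']:<10} {stage['elapsed_s']:6.2f}s  {extra}")
print("\noutputs:", ", ".join(manifest["outputs"]))
print(json.dumps({"seed": manifest["seed"]}))
print("\nEvery file listed above now sits in scratch/pipeline_demo; the "
      "same run is reproducible byte-for-byte from this config and seed.")
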