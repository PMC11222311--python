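"""End-to-end orchestration: simulate -> cohort -> indices -> trajectory ->
associate -> interact, with a run manifest.

Each stage reads/writes plain CSV/JSON under the run's output directory; the
manifest records inputs, outputs, seeds, per-stage row counts and timings.
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, cohort, indices, interaction, lgmm, simulate

ALL_STAGES = ("simulate", "cohort", "indices", "trajectory", "associate",
              "interact")

DEFAULT_EXPOSURES = ("baseline_stratum", "mbg_stratum", "mag_high",
                     "mage_high", "gli_high", "lage_high", "trajectory_class")

DEFAULT_PAIRS = (("mbg", "inr"), ("mag", "inr"), ("gli", "inr"),
                 ("mbg", "egfr"), ("mag", "egfr"), ("gli", "egfr"))


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 20240620
    stages: tuple = ALL_STAGES
    n_patients: int = 1951
    threshold_mode: str = "median"
    kmax: int = 5
    n_restarts: int = 2
    models: tuple = (1, 2, 3, 4, 5)
    exposures: tuple = DEFAULT_EXPOSURES
    subgroups: tuple = tuple(association.SUBGROUP_DEFS)
    pairs: tuple = DEFAULT_PAIRS
    interaction_method: str = "delta"
    bootstrap_b: int = 500
    records_file: str | None = None   # skip simulate and read these instead
    glucose_file: str | None = None
    sim_overrides: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "outputs": []}
    records = glucose = None
    index_df = None
    selected_k = None
    assignments = None

    def _stage(name):
        return {"stage": name, "started": time.time()}

    def _done(entry, **info):
        entry["elapsed_s"] = round(time.time() - entry.pop("started"), 3)
        entry.update(info)
        manifest["stages"].append(entry)

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)
        return path

    try:
        if "simulate" in config.stages:
            entry = _stage("simulate")
            cfg = simulate.SimulationConfig(n_patients=config.n_patients,
                                            seed=config.seed,
                                            **config.sim_overrides)
            data = simulate.generate_cohort(cfg)
            records, glucose = data.records, data.glucose
            _write(records, "records.csv")
            _write(glucose, "glucose.csv")
            _write(data.true_classes.reset_index(), "true_classes.csv")
            _done(entry, n_records=len(records))
        elif config.records_file:
            records = pd.read_csv(config.records_file)
            if config.glucose_file:
                glucose = pd.read_csv(config.glucose_file)

        if "cohort" in config.stages:
            entry = _stage("cohort")
            kept, log = cohort.apply_exclusions(records)
            records = kept
            _write(kept, "cohort_kept.csv")
            _write(log, "exclusion_log.csv")
            _done(entry, n_kept=len(kept), n_excluded=len(log))

        if "indices" in config.stages:
            entry = _stage("indices")
            index_df = indices.index_table(glucose,
                                           threshold_mode=config.threshold_mode)
            _write(index_df, "indices.csv")
            # refresh records strata from the index table
            merge_cols = [c for c in index_df.columns if c != "patient_id"]
            records = (records.drop(columns=merge_cols, errors="ignore")
                       .merge(index_df, on="patient_id"))
            _done(entry, n_patients=len(index_df))

        if "trajectory" in config.stages:
            entry = _stage("trajectory")
            kept_glucose = glucose[glucose["patient_id"].isin(records["patient_id"])]
            models = {}
            for k in range(1, config.kmax + 1):
                models[k] = lgmm.fit_lgmm(kept_glucose, k, seed=config.seed,
                                          n_restarts=config.n_restarts)
            report = lgmm.select_classes(models)
            _write(report.table, "class_selection.csv")
            selected_k = report.selected_k
            if selected_k is not None:
                model = models[selected_k]
                assignments = lgmm.assign_classes(model)
                _write(assignments, "class_assignments.csv")
                model_json = {
                    "n_classes": model.n_classes,
                    "coefficients_per_hour": model.coefficients.tolist(),
                    "mixing_proportions": model.mixing_proportions.tolist(),
                    "random_intercept_var": model.random_intercept_var,
                    "residual_var": model.residual_var,
                    "log_likelihood": model.log_likelihood,
                    "aic": model.aic, "bic": model.bic,
                    "entropy": model.entropy,
                }
                (out / "trajectory_model.json").write_text(
                    json.dumps(model_json, indent=2))
                manifest["outputs"].append("trajectory_model.json")
                records = records.merge(
                    assignments.rename(columns={"map_class": "trajectory_class"})
                    [["patient_id", "trajectory_class"]],
                    on="patient_id", how="left")
            _done(entry, selected_k=selected_k)

        if "associate" in config.stages:
            entry = _stage("associate")
            exposures = [e for e in config.exposures
                         if e != "trajectory_class" or "trajectory_class" in records]
            tables = [association.run_model_ladder(records, e, config.models)
                      for e in exposures]
            ladder = pd.concat(tables, ignore_index=True)
            _write(ladder, "model_ladder.csv")
            sub_tables = []
            for sg in config.subgroups:
                for e in ("mbg_stratum", "mag_high", "gli_high"):
                    t = association.subgroup_analysis(records, e, sg)
                    t.insert(0, "exposure", e)
                    sub_tables.append(t)
            _write(pd.concat(sub_tables, ignore_index=True), "subgroups.csv")
            _done(entry, n_models=len(ladder))

        if "interact" in config.stages:
            entry = _stage("interact")
            cutpoints = "median" if config.threshold_mode == "median" else None
            table = interaction.interaction_table(
                records, config.pairs, cutpoints=cutpoints,
                method=config.interaction_method,
                n_boot=config.bootstrap_b, seed=config.seed)
            _write(table, "interactions.csv")
            _done(entry, n_pairs=len(table))
    except Exception as exc:
        stage_name = "unknown"
        if "entry" in locals() and "stage" in entry:
            stage_name = entry["stage"]
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
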