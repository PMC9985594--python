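"""Staged pipeline: simulate -> build-cohort -> classify -> patterns -> summarize.

Each stage reads CSV artifacts written by the previous one, writes its own,
and appends an entry (input/output hashes, row counts, config hash) to a
JSON-lines manifest, so a rerun on unchanged inputs is verifiably
idempotent and every threshold in force is auditable from the run log.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classifier, cohort, patterns, simulate, summaries
from .ehr_model import read_tables

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("ocspatterns")

STAGES = ("simulate", "build-cohort", "classify", "patterns", "summarize")

DEFAULT_CONFIG: dict = {
    "io": {"dayfirst": False},
    "simulation": {
        "n_patients": 200,
        "seed": 0,
        "strict_gaps": True,
    },
    "cohort": {
        "concurrency_window_days": 91,
        "baseline_days": 365,
        "min_age_years": 4,
        "adult_age_years": 18,
        "strict_adult_concurrency": False,
    },
    "classifier": {
        "dose_high_threshold_mg": 20.0,
        "dose_low_threshold_mg": 10.0,
        "concurrency_window_days": 14,
        "annual_nonintermittent_max": 2,
        "annual_window_days": 365,
    },
    "stratifiers": {"baseline_days": 365},
}


class PipelineError(RuntimeError):
    pass


def _merge(defaults: Mapping, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in out:
            raise PipelineError(f"unknown config key: {where}")
        if isinstance(out[key], dict):
            if not isinstance(value, Mapping):
                raise PipelineError(f"config section {where} must be a mapping")
            out[key] = _merge(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    """Default-merged run configuration; unknown keys are rejected."""
    import yaml

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _require(outdir: Path, names: Sequence[str], needed_stage: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise PipelineError(
                f"missing artifact {name!r}: run stage '{needed_stage}' first")


def _classifier_config(cfg: Mapping) -> classifier.ClassifierConfig:
    return classifier.ClassifierConfig(**cfg["classifier"])


def _cohort_config(cfg: Mapping) -> cohort.CohortConfig:
    return cohort.CohortConfig(**cfg["cohort"])


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: Mapping, outdir: Path) -> dict:
    sim_cfg = simulate.SimulationConfig(**cfg["simulation"])
    bundle = simulate.generate(sim_cfg)
    for name, df in (("patients", bundle.patients),
                     ("prescriptions", bundle.prescriptions),
                     ("events", bundle.events),
                     ("ground_truth", bundle.ground_truth)):
        _write_csv(df, outdir / f"{name}.csv")
    return {"outputs": ["patients.csv", "prescriptions.csv", "events.csv",
                        "ground_truth.csv"],
            "row_counts": {"patients": len(bundle.patients),
                           "prescriptions": len(bundle.prescriptions),
                           "events": len(bundle.events)}}


def _read_inputs(cfg: Mapping, outdir: Path):
    return read_tables(outdir / "patients.csv", outdir / "prescriptions.csv",
                       outdir / "events.csv", dayfirst=cfg["io"]["dayfirst"])


def _stage_build_cohort(cfg: Mapping, outdir: Path) -> dict:
    _require(outdir, ["patients.csv", "prescriptions.csv", "events.csv"], "simulate")
    bundle = _read_inputs(cfg, outdir)
    ccfg = _cohort_config(cfg)
    log.info("cohort windows: concurrency=%sd baseline=%sd",
             ccfg.concurrency_window_days, ccfg.baseline_days)
    cohort_df, attrition = cohort.build_cohort(
        bundle.patients, bundle.prescriptions, bundle.events, ccfg)
    _write_csv(cohort_df, outdir / "cohort.csv")
    _write_csv(attrition, outdir / "attrition.csv")
    _write_csv(bundle.rejects, outdir / "rejects.csv")
    for _, row in attrition.iterrows():
        log.info("attrition: %-28s removed=%-6s remaining=%s",
                 row["rule"], row["n_removed"], row["n_remaining"])
    return {"inputs": ["patients.csv", "prescriptions.csv", "events.csv"],
            "outputs": ["cohort.csv", "attrition.csv", "rejects.csv"],
            "row_counts": {"patients_in": len(bundle.patients),
                           "eligible": int(cohort_df["eligible"].sum()),
                           "rejects": len(bundle.rejects)}}


def _stage_classify(cfg: Mapping, outdir: Path) -> dict:
    _require(outdir, ["cohort.csv"], "build-cohort")
    bundle = _read_inputs(cfg, outdir)
    cohort_df = pd.read_csv(outdir / "cohort.csv", parse_dates=["index_date"])
    kcfg = _classifier_config(cfg)
    log.info("classifier thresholds: dose_high=%s dose_low=%s window=%sd annual_max=%s",
             kcfg.dose_high_threshold_mg, kcfg.dose_low_threshold_mg,
             kcfg.concurrency_window_days, kcfg.annual_nonintermittent_max)
    scripts, patient_use = classifier.classify_cohort(
        cohort_df, bundle.prescriptions, bundle.events, kcfg)
    _write_csv(scripts, outdir / "scripts_classified.csv")
    _write_csv(patient_use, outdir / "patient_use.csv")
    n_ocs_in = int((bundle.prescriptions["therapy_class"] == "OCS").sum())
    return {"inputs": ["cohort.csv", "prescriptions.csv", "events.csv"],
            "outputs": ["scripts_classified.csv", "patient_use.csv"],
            "row_counts": {"ocs_scripts_in": n_ocs_in,
                           "scripts_labeled": len(scripts),
                           "patients_labeled": len(patient_use)}}


def _stage_patterns(cfg: Mapping, outdir: Path) -> dict:
    _require(outdir, ["scripts_classified.csv", "patient_use.csv"], "classify")
    scripts = pd.read_csv(outdir / "scripts_classified.csv", parse_dates=["date"])
    patient_use = pd.read_csv(outdir / "patient_use.csv")
    profiles = patterns.profiles_frame(scripts, patient_use)
    _write_csv(profiles, outdir / "patterns.csv")
    return {"inputs": ["scripts_classified.csv", "patient_use.csv"],
            "outputs": ["patterns.csv"],
            "row_counts": {"patients_profiled": len(profiles)}}


def _stage_summarize(cfg: Mapping, outdir: Path) -> dict:
    _require(outdir, ["patterns.csv"], "patterns")
    _require(outdir, ["cohort.csv"], "build-cohort")
    profiles = pd.read_csv(outdir / "patterns.csv")
    cohort_df = pd.read_csv(outdir / "cohort.csv", parse_dates=["index_date"])
    bundle = _read_inputs(cfg, outdir)

    table = summaries.summarize_patterns(profiles)
    _write_csv(table, outdir / "pattern_summary.csv")

    # baseline stratifiers for the profiled patients
    base_days = cfg["stratifiers"]["baseline_days"]
    idx = cohort_df.set_index("patient_id")
    rx_by_pat = dict(tuple(bundle.prescriptions.groupby("patient_id", sort=False)))
    empty_rx = bundle.prescriptions.iloc[0:0]
    strat_rows = []
    for pid in profiles["patient_id"]:
        index_date = idx.loc[pid, "index_date"]
        rx = rx_by_pat.get(pid, empty_rx)
        base = summaries.baseline_window(rx, index_date, base_days)
        strat_rows.append({
            "patient_id": pid,
            "gina_step": summaries.assign_gina_step(base),
            "saba_band": summaries.count_saba_fills(rx, index_date, base_days),
            "age_band": summaries.age_band(idx.loc[pid, "age_at_index"]),
        })
    strat = pd.DataFrame(strat_rows,
                         columns=["patient_id", "gina_step", "saba_band", "age_band"])
    _write_csv(strat, outdir / "stratifiers.csv")

    merged = profiles.merge(strat, on="patient_id")
    chisq_rows = []
    for name in ("saba_band", "age_band", "gina_step"):
        try:
            res = summaries.crosstab_and_chisq(merged["simplified_label"], merged[name])
        except ValueError:
            continue
        res.table.to_csv(outdir / f"crosstab_{name}.csv")
        chisq_rows.append({"stratifier": name, "statistic": res.statistic,
                           "dof": res.dof, "pvalue": res.pvalue})
    _write_csv(pd.DataFrame(chisq_rows), outdir / "chisq_report.csv")

    # simple dose-per-script histogram (5 mg prednisolone-equivalent bins)
    if (outdir / "scripts_classified.csv").exists():
        scripts = pd.read_csv(outdir / "scripts_classified.csv")
        doses = scripts["pred_equiv_mg_per_day"].dropna()
        if len(doses):
            bins = pd.cut(doses, bins=range(0, int(doses.max()) + 10, 5))
            hist = bins.value_counts().sort_index()
            hist_df = pd.DataFrame({"bin": hist.index.astype(str), "n": hist.values})
            _write_csv(hist_df, outdir / "dose_histogram.csv")

    return {"inputs": ["patterns.csv", "cohort.csv", "prescriptions.csv"],
            "outputs": ["pattern_summary.csv", "stratifiers.csv", "chisq_report.csv"],
            "row_counts": {"summary_rows": len(table)}}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "build-cohort": _stage_build_cohort,
    "classify": _stage_classify,
    "patterns": _stage_patterns,
    "summarize": _stage_summarize,
}


def run_pipeline(config: Mapping | None = None,
                 stages: Sequence[str] | None = None,
                 outdir: str | Path = "output") -> list[dict]:
    """Run the requested stages in order; returns the manifest entries.

    Later stages may run alone provided their upstream artifacts already
    exist in ``outdir``; otherwise an error names the stage to run first.
    """
    cfg = config if config is not None else load_config()
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {s!r}")
    stages.sort(key=STAGES.index)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    (outdir / "config_effective.json").write_text(cfg_text)
    config_hash = hashlib.sha256(cfg_text.encode()).hexdigest()

    manifest_path = outdir / "manifest.jsonl"
    entries = []
    with open(manifest_path, "a") as mf:
        for stage in stages:
            log.info("running stage %s", stage)
            info = _STAGE_FUNCS[stage](cfg, outdir)
            entry = {
                "stage": stage,
                "config_hash": config_hash,
                "inputs": {n: _sha256(outdir / n) for n in info.get("inputs", [])},
                "outputs": {n: _sha256(outdir / n) for n in info.get("outputs", [])},
                "row_counts": info.get("row_counts", {}),
            }
            mf.write(json.dumps(entry, sort_keys=True) + "\n")
            entries.append(entry)
    return entries
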