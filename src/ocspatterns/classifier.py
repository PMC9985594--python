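"""Stepwise classification of OCS prescriptions: intermittent vs long-term.

Each script is passed through four steps, starting with the most definitive
information and stopping at the first decisive one:

1. *instruction* — the free-text dosing instruction is matched against an
   ordered rulebook of taper/short-course phrases (intermittent) and
   maintenance phrases (long-term).
2. *dose* — the prednisolone-equivalent daily dose: at or above the high
   threshold the script is an acute burst (intermittent); at or below the
   low threshold it is maintenance (long-term); in between, undecided.
3. *concurrent_event* — a lower respiratory tract infection or asthma
   exacerbation within a symmetric window of the script date supports an
   acute course (intermittent).
4. *annual_count* — scripts still undecided are labeled by how many
   undecided scripts fall in the trailing 365-day window: few implies
   occasional acute use (intermittent), many implies probable maintenance
   (long-term).

The fall-through design maximizes specificity for intermittent use: any
script that might plausibly be maintenance ends up labeled long-term.
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .ehr_model import (
    ParsedInstruction,
    PrescriptionRecord,
    UnknownSubstanceError,
    daily_dose_from_script,
    load_ddd_table,
    parse_dosage,
    to_prednisolone_equivalent,
)

__all__ = [
    "Rule",
    "ClassifierConfig",
    "load_rulebook",
    "parse_instruction",
    "classify_by_dose",
    "classify_by_concurrent_event",
    "classify_by_annual_count",
    "classify_patient",
    "classify_cohort",
]

INTERMITTENT = "intermittent"
LONG_TERM = "long_term"
UNDECIDED = "undecided"


@dataclass(frozen=True)
class Rule:
    priority: int
    pattern: re.Pattern
    verdict: str


def load_rulebook(path=None) -> tuple[Rule, ...]:
    """Load the ordered instruction rulebook (CSV: priority, pattern, verdict)."""
    if path is None:
        path = str(importlib.resources.files("ocspatterns.data") / "instruction_rules.csv")
    df = pd.read_csv(path).sort_values("priority")
    rules = []
    for _, row in df.iterrows():
        verdict = str(row["verdict"])
        if verdict not in (INTERMITTENT, LONG_TERM, UNDECIDED):
            raise ValueError(f"bad verdict {verdict!r} in rulebook")
        rules.append(Rule(int(row["priority"]),
                          re.compile(str(row["pattern"]), re.IGNORECASE), verdict))
    return tuple(rules)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the stepwise algorithm.

    Dose thresholds are prednisolone-equivalent mg/day; the defaults follow
    the NICE convention that adult acute courses run 40-50 mg/day while
    typical maintenance is <=10 mg/day.
    """

    dose_high_threshold_mg: float = 20.0
    dose_low_threshold_mg: float = 10.0
    concurrency_window_days: int = 14
    annual_nonintermittent_max: int = 2
    annual_window_days: int = 365
    rulebook: tuple[Rule, ...] = field(default_factory=load_rulebook)

    def __post_init__(self) -> None:
        if not self.dose_low_threshold_mg < self.dose_high_threshold_mg:
            raise ValueError("dose_low_threshold_mg must be < dose_high_threshold_mg")
        if self.concurrency_window_days <= 0 or self.annual_window_days <= 0:
            raise ValueError("windows must be positive")


def parse_instruction(text: str | None, rulebook: Sequence[Rule]) -> str:
    """First matching rule's verdict; undecided for empty or unmatched text."""
    if not text:
        return UNDECIDED
    for rule in rulebook:
        if rule.pattern.search(text):
            return rule.verdict
    return UNDECIDED


def classify_by_dose(pred_equiv_mg_per_day: float, config: ClassifierConfig) -> str:
    if pred_equiv_mg_per_day < 0:
        raise ValueError("negative dose")
    if pred_equiv_mg_per_day >= config.dose_high_threshold_mg:
        return INTERMITTENT
    if pred_equiv_mg_per_day <= config.dose_low_threshold_mg:
        return LONG_TERM
    return UNDECIDED


def classify_by_concurrent_event(
    rx_date: pd.Timestamp, events: pd.DataFrame, window_days: int
) -> str:
    """Intermittent iff an LRTI or exacerbation lies within +/-window of the script."""
    acute = events.loc[events["category"].isin(["lrti", "exacerbation"]), "date"]
    if acute.empty:
        return UNDECIDED
    if ((acute - rx_date).abs() <= pd.Timedelta(days=window_days)).any():
        return INTERMITTENT
    return UNDECIDED


def classify_by_annual_count(
    undecided_dates: Sequence[pd.Timestamp], config: ClassifierConfig
) -> list[str]:
    """Label scripts left undecided by all earlier steps.

    For each script (in date order) the number of undecided scripts in the
    trailing window ending at (and including) it is counted; up to
    ``annual_nonintermittent_max`` such scripts per window are still
    plausibly acute (intermittent), more imply maintenance (long-term).
    """
    dates = sorted(pd.Timestamp(d) for d in undecided_dates)
    window = pd.Timedelta(days=config.annual_window_days)
    labels = []
    for i, d in enumerate(dates):
        n_in_window = sum(1 for prev in dates[: i + 1] if d - prev < window)
        labels.append(INTERMITTENT if n_in_window <= config.annual_nonintermittent_max
                      else LONG_TERM)
    return labels


def classify_patient(
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    config: ClassifierConfig = None,
    ddd_table: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Label every OCS script of one patient and derive the patient-level use.

    Returns (scripts, patient_use) where scripts has one row per OCS
    prescription with columns date, label, decision_step and
    pred_equiv_mg_per_day (NaN when unknown), and patient_use is
    ``intermittent_only`` iff every script is labeled intermittent, else
    ``any_long_term``.
    """
    if config is None:
        config = ClassifierConfig()
    if ddd_table is None:
        ddd_table = load_ddd_table()
    ocs = prescriptions.loc[prescriptions["therapy_class"] == "OCS"]
    if ocs.empty:
        raise ValueError("patient has no OCS prescriptions to classify")
    ocs = ocs.sort_values("date", kind="stable")

    rows = []
    pending = []  # (row position, date) of scripts undecided after steps 1-3
    for _, rx in ocs.iterrows():
        parsed = parse_dosage(rx.get("instruction_text", ""))
        dose = _pred_equiv(rx, parsed, ddd_table)
        verdict = parse_instruction(rx.get("instruction_text", ""), config.rulebook)
        step = "instruction"
        if verdict == UNDECIDED and dose is not None:
            verdict = classify_by_dose(dose, config)
            step = "dose"
        if verdict == UNDECIDED:
            verdict = classify_by_concurrent_event(rx["date"], events,
                                                   config.concurrency_window_days)
            step = "concurrent_event"
        if verdict == UNDECIDED:
            step = "annual_count"
            pending.append(len(rows))
        rows.append({
            "date": rx["date"],
            "label": verdict,
            "decision_step": step,
            "pred_equiv_mg_per_day": dose if dose is not None else float("nan"),
        })
    if pending:
        labels = classify_by_annual_count([rows[i]["date"] for i in pending], config)
        for i, lab in zip(pending, labels):
            rows[i]["label"] = lab
    scripts = pd.DataFrame(rows)
    patient_use = ("intermittent_only" if (scripts["label"] == INTERMITTENT).all()
                   else "any_long_term")
    return scripts, patient_use


def _pred_equiv(rx: pd.Series, parsed: ParsedInstruction, ddd_table) -> float | None:
    """Prednisolone-equivalent mg/day for one script row, or None if unknowable."""
    strength = rx.get("strength_mg_per_unit")
    quantity = rx.get("quantity_units")
    record = PrescriptionRecord(
        patient_id=str(rx.get("patient_id", "")),
        date=rx["date"],
        drug=str(rx["drug"]),
        therapy_class="OCS",
        strength_mg_per_unit=None if pd.isna(strength) else float(strength),
        quantity_units=None if pd.isna(quantity) else float(quantity),
        instruction_text=str(rx.get("instruction_text", "") or ""),
    )
    dose = daily_dose_from_script(record, parsed)
    if dose is None:
        return None
    try:
        return to_prednisolone_equivalent(record.drug, dose, ddd_table)
    except UnknownSubstanceError:
        return None


def classify_cohort(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    config: ClassifierConfig = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every eligible OCS-arm patient in a cohort.

    Returns (scripts, patients): per-script labels with patient_id attached,
    and a per-patient table with patient_use.
    """
    if config is None:
        config = ClassifierConfig()
    ddd = load_ddd_table()
    eligible = cohort.loc[cohort["eligible"] & (cohort["arm"] == "ocs"), "patient_id"]
    rx_by_pat = dict(tuple(prescriptions.groupby("patient_id", sort=False)))
    ev_by_pat = dict(tuple(events.groupby("patient_id", sort=False)))
    empty_ev = events.iloc[0:0]
    script_frames, patient_rows = [], []
    for pid in eligible:
        scripts, use = classify_patient(rx_by_pat[pid], ev_by_pat.get(pid, empty_ev),
                                        config, ddd)
        scripts.insert(0, "patient_id", pid)
        script_frames.append(scripts)
        patient_rows.append({"patient_id": pid, "patient_use": use,
                             "n_ocs_scripts": len(scripts)})
    if script_frames:
        all_scripts = pd.concat(script_frames, ignore_index=True)
    else:
        all_scripts = pd.DataFrame(columns=[
            "patient_id", "date", "label", "decision_step", "pred_equiv_mg_per_day"])
    patients = pd.DataFrame(patient_rows,
                            columns=["patient_id", "patient_use", "n_ocs_scripts"])
    return all_scripts, patients
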