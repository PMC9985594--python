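"""Cohort construction: inclusion/exclusion rules, index date and study arm.

The index date is the first OCS prescription.  Eligibility requires age >=4
years at index, an asthma event (diagnosis, consultation or asthma-therapy
prescription) concurrent with the index date, and at least 12 months of
registration before it.  Adults ever diagnosed with one of ten chronic
OCS-treated conditions are excluded; minors only when such a diagnosis is
concurrent with an OCS prescription.  Every removal is accounted for in an
attrition log.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .ehr_model import EXCLUSION_CONDITIONS

__all__ = [
    "CohortConfig",
    "ASTHMA_THERAPY_CLASSES",
    "age_at",
    "find_index_date",
    "check_inclusion",
    "check_exclusion_conditions",
    "build_cohort",
]

#: therapy classes whose prescriptions count as an "asthma event"
ASTHMA_THERAPY_CLASSES = frozenset({"SABA", "ICS", "ICS_LABA", "LTRA", "LAMA", "biologic"})

#: attrition reasons in the fixed rule-application order
ATTRITION_REASONS = (
    "age_below_minimum",
    "no_concurrent_asthma_event",
    "insufficient_baseline",
    "exclusion_condition",
)


@dataclass(frozen=True)
class CohortConfig:
    """Windows (whole days) governing eligibility.

    ``concurrency_window_days`` implements the "within 3 months" rule;
    ``baseline_days`` the 12-month pre-index registration requirement.
    """

    concurrency_window_days: int = 91
    baseline_days: int = 365
    min_age_years: int = 4
    adult_age_years: int = 18
    #: adults: exclude on condition ever present (False) or only when
    #: concurrent with an OCS script (True)
    strict_adult_concurrency: bool = False


def age_at(birth_date: pd.Timestamp, on_date: pd.Timestamp) -> int:
    """Completed years of age on a given date."""
    birth_date = pd.Timestamp(birth_date)
    on_date = pd.Timestamp(on_date)
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def find_index_date(prescriptions: pd.DataFrame) -> pd.Timestamp | None:
    """Earliest OCS prescription date for one patient, or None if no OCS."""
    ocs = prescriptions.loc[prescriptions["therapy_class"] == "OCS", "date"]
    if ocs.empty:
        return None
    return ocs.min()


def _has_asthma_event_near(
    index_date: pd.Timestamp,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    window_days: int,
) -> bool:
    window = pd.Timedelta(days=window_days)
    ev = events.loc[events["category"].isin(["asthma_diagnosis", "asthma_consultation"]), "date"]
    if not ev.empty and ((pd.to_datetime(ev) - index_date).abs() <= window).any():
        return True
    med = prescriptions.loc[prescriptions["therapy_class"].isin(ASTHMA_THERAPY_CLASSES), "date"]
    return bool(not med.empty
                and ((pd.to_datetime(med) - index_date).abs() <= window).any())


def check_inclusion(
    patient: pd.Series,
    index_date: pd.Timestamp,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> tuple[bool, str | None]:
    """Inclusion rules in fixed order: age, concurrent asthma event, baseline.

    Returns (eligible, reason); reason names the first failing rule.
    """
    if age_at(patient["birth_date"], index_date) < config.min_age_years:
        return False, "age_below_minimum"
    if not _has_asthma_event_near(index_date, events, prescriptions,
                                  config.concurrency_window_days):
        return False, "no_concurrent_asthma_event"
    if patient["registration_start"] > index_date - pd.Timedelta(days=config.baseline_days):
        return False, "insufficient_baseline"
    return True, None


def check_exclusion_conditions(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    age_at_index: int,
    config: CohortConfig = CohortConfig(),
) -> tuple[bool, str | None]:
    """Chronic-condition exclusion.

    Adults (>=18 at index): any listed condition ever recorded excludes
    (optionally restricted to diagnoses concurrent with an OCS script).
    Minors: excluded only when a listed diagnosis is concurrent (within the
    configured window) with an OCS prescription.
    """
    cond = events.loc[events["category"].str.startswith("exclusion_condition:")]
    if cond.empty:
        return False, None
    adult = age_at_index >= config.adult_age_years
    if adult and not config.strict_adult_concurrency:
        name = cond.iloc[0]["category"].split(":", 1)[1]
        return True, name
    ocs_dates = prescriptions.loc[prescriptions["therapy_class"] == "OCS", "date"]
    window = pd.Timedelta(days=config.concurrency_window_days)
    for _, row in cond.iterrows():
        if ((ocs_dates - row["date"]).abs() <= window).any():
            return True, row["category"].split(":", 1)[1]
    return False, None


def build_cohort(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all eligibility rules to every patient.

    Returns (cohort, attrition).  The cohort has one row per input patient
    with columns patient_id, arm (ocs/non_ocs), index_date, age_at_index,
    eligible, exclusion_reason.  The attrition log reports, in rule order,
    the number removed per reason; eligible + removed = input patients.

    For non-OCS-arm patients (no OCS script ever) the reference date for the
    concurrency and baseline rules is registration_start + baseline_days.
    """
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup!r} in patients table")

    rx_by_pat = dict(tuple(prescriptions.groupby("patient_id", sort=False)))
    ev_by_pat = dict(tuple(events.groupby("patient_id", sort=False)))
    empty_rx = prescriptions.iloc[0:0]
    empty_ev = events.iloc[0:0]

    rows = []
    for _, patient in patients.iterrows():
        pid = patient["patient_id"]
        rx = rx_by_pat.get(pid, empty_rx)
        ev = ev_by_pat.get(pid, empty_ev)
        index_date = find_index_date(rx)
        if index_date is None:
            arm = "non_ocs"
            index_date = patient["registration_start"] + pd.Timedelta(days=config.baseline_days)
        else:
            arm = "ocs"
        age = age_at(patient["birth_date"], index_date)
        eligible, reason = check_inclusion(patient, index_date, ev, rx, config)
        if eligible:
            excluded, cond = check_exclusion_conditions(ev, rx, age, config)
            if excluded:
                eligible, reason = False, f"exclusion_condition:{cond}"
        rows.append({
            "patient_id": pid,
            "arm": arm,
            "index_date": index_date,
            "age_at_index": age,
            "eligible": eligible,
            "exclusion_reason": reason,
        })
    cohort = pd.DataFrame(rows, columns=[
        "patient_id", "arm", "index_date", "age_at_index", "eligible", "exclusion_reason",
    ])

    reasons = cohort["exclusion_reason"].fillna("").astype(str)
    counts = {
        r: int((reasons == r).sum()) if r != "exclusion_condition"
        else int(reasons.str.startswith("exclusion_condition:").sum())
        for r in ATTRITION_REASONS
    }
    attrition = pd.DataFrame({
        "rule": list(ATTRITION_REASONS) + ["eligible"],
        "n_removed": [counts[r] for r in ATTRITION_REASONS] + [0],
        "n_remaining": np.nan,
    })
    total = len(cohort)
    remaining = total
    n_remaining = []
    for r in ATTRITION_REASONS:
        remaining -= counts[r]
        n_remaining.append(remaining)
    n_remaining.append(remaining)
    attrition["n_remaining"] = n_remaining
    assert remaining == int(cohort["eligible"].sum())
    return cohort, attrition
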