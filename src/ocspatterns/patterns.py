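"""Gap-category sequencing of intermittent OCS courses.

Consecutive course dates define gaps classified as frequent (<90 days),
moderately frequent (90-181), infrequent (182-364) or sporadic (>=365).
Patients with a single prescription ever are "once-only".  The set of
categories observed across the whole follow-up yields a detailed
combination label (16 possible) and a simplified three-way label:
once-only / less frequent / frequent, where any <90-day gap anywhere in
follow-up makes the patient "frequent".
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GAP_CATEGORIES",
    "PatternProfile",
    "ALL_DETAILED_LABELS",
    "collapse_courses",
    "categorize_gap",
    "detailed_label",
    "derive_profile",
    "simplify",
    "profiles_frame",
]

#: gap categories ordered longest-cycle-first (the canonical naming order)
GAP_CATEGORIES = ("sporadic", "infrequent", "moderately_frequent", "frequent")

_CATEGORY_WORDS = {
    "sporadic": "sporadic",
    "infrequent": "infrequent",
    "moderately_frequent": "moderately frequent",
    "frequent": "frequent",
}

ONCE_ONLY = "once_only"
LESS_FREQUENT = "less_frequent"
FREQUENT = "frequent"
SIMPLIFIED_LABELS = (ONCE_ONLY, LESS_FREQUENT, FREQUENT)


def collapse_courses(dates: Iterable) -> list[pd.Timestamp]:
    """Sorted distinct course dates (same-day scripts merged into one course)."""
    out = sorted({pd.Timestamp(d) for d in dates})
    if not out:
        raise ValueError("no course dates: patient should have >=1 intermittent script")
    return out


def categorize_gap(days: int) -> str:
    """Map a positive gap (whole days) to its category."""
    if days < 1:
        raise ValueError("gap must be >= 1 day")
    if days < 90:
        return "frequent"
    if days <= 181:
        return "moderately_frequent"
    if days <= 364:
        return "infrequent"
    return "sporadic"


def detailed_label(n_courses: int, categories: frozenset | set) -> str:
    """Canonical combination label.

    Single prescription -> "Once-only"; single category -> "<Category> only"
    (except the sporadic-only row, conventionally just "Sporadic"); mixtures
    are named longest-cycle-first, e.g. "Sporadic, infrequent and frequent".
    """
    if n_courses == 1:
        if categories:
            raise ValueError("once-only patients have no gaps")
        return "Once-only"
    if not categories:
        raise ValueError("multi-course patients must have >=1 gap category")
    ordered = [_CATEGORY_WORDS[c] for c in GAP_CATEGORIES if c in categories]
    if len(ordered) == 1:
        word = ordered[0]
        if word == "sporadic":
            return "Sporadic"
        return f"{word.capitalize()} only"
    head = ", ".join(ordered[:-1])
    label = f"{head} and {ordered[-1]}"
    return label[0].upper() + label[1:]


#: the 16 possible detailed labels (once-only + all nonempty category subsets)
ALL_DETAILED_LABELS = tuple(
    ["Once-only"]
    + [
        detailed_label(2, frozenset(sub))
        for r in range(1, 5)
        for sub in combinations(GAP_CATEGORIES, r)
    ]
)


@dataclass(frozen=True)
class PatternProfile:
    patient_id: str
    n_courses: int
    categories_present: frozenset
    detailed_label: str
    simplified_label: str

    @property
    def mixed(self) -> bool:
        return len(self.categories_present) > 1


def derive_profile(course_dates: Sequence, patient_id: str = "") -> PatternProfile:
    """Profile one patient from the dates of their intermittent OCS courses."""
    courses = collapse_courses(course_dates)
    gaps = [(b - a).days for a, b in zip(courses, courses[1:])]
    categories = frozenset(categorize_gap(g) for g in gaps)
    label = detailed_label(len(courses), categories)
    profile = PatternProfile(
        patient_id=patient_id,
        n_courses=len(courses),
        categories_present=categories,
        detailed_label=label,
        simplified_label="",
    )
    return PatternProfile(
        patient_id=patient_id,
        n_courses=len(courses),
        categories_present=categories,
        detailed_label=label,
        simplified_label=simplify(profile),
    )


def simplify(profile: PatternProfile) -> str:
    """Three-way collapse: once-only / less frequent / frequent."""
    if profile.n_courses == 1:
        return ONCE_ONLY
    if "frequent" in profile.categories_present:
        return FREQUENT
    return LESS_FREQUENT


def profiles_frame(scripts: pd.DataFrame, patient_use: pd.DataFrame) -> pd.DataFrame:
    """Per-patient pattern table for intermittent-only patients.

    ``scripts`` is the per-script classification output; only patients whose
    every script is intermittent enter the pattern analysis.
    """
    keep = set(patient_use.loc[patient_use["patient_use"] == "intermittent_only",
                               "patient_id"])
    sub = scripts.loc[scripts["patient_id"].isin(keep)]
    rows = []
    for pid, grp in sub.groupby("patient_id", sort=True):
        p = derive_profile(grp["date"].tolist(), patient_id=pid)
        row = {
            "patient_id": pid,
            "n_courses": p.n_courses,
            "n_scripts": len(grp),
            "detailed_label": p.detailed_label,
            "simplified_label": p.simplified_label,
            "mixed": p.mixed,
        }
        for c in GAP_CATEGORIES:
            row[f"has_{c}"] = c in p.categories_present
        rows.append(row)
    cols = ["patient_id", "n_courses", "n_scripts", "detailed_label",
            "simplified_label", "mixed"] + [f"has_{c}" for c in GAP_CATEGORIES]
    return pd.DataFrame(rows, columns=cols)
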