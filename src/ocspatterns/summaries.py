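"""Baseline stratifiers and pattern summary tables.

Stratifiers are assessed strictly within the 365 days before the index
date: GINA 2020 treatment step (derived from controller/reliever therapy
records through a bundled rule table), SABA fill band (0 / 1-2 / >=3) and
age band (child >=4-<12, adolescent >=12-<18, adult >=18).  Summary tables
mirror the detailed-pattern taxonomy with "Any <category>" super-rows,
counts, percentages (one decimal, half away from zero), mean (SD) and
median (IQR, linear-interpolation quartiles) numbers of prescriptions.
Cross-tabulations are tested with Pearson's chi-square (no continuity
correction).
"""
from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ehr_model import parse_dosage
from .patterns import ALL_DETAILED_LABELS, GAP_CATEGORIES

__all__ = [
    "percent",
    "age_band",
    "saba_band",
    "count_saba_fills",
    "baseline_window",
    "ics_dose_band",
    "assign_gina_step",
    "summarize_patterns",
    "aggregate_detailed_counts",
    "ChiSquareResult",
    "crosstab_and_chisq",
    "chisq_from_table",
    "load_published_pattern_table",
]

AGE_BANDS = ("child", "adolescent", "adult")
SABA_BANDS = ("0", "1-2", ">=3")
GINA_STEPS = (0, 1, 2, 3, 4, 5)  # 0 = no asthma medication

#: ICS daily-dose bands in beclometasone-equivalent ug/day (adult convention)
ICS_LOW_MAX_UG = 400.0
ICS_MEDIUM_MAX_UG = 800.0


def percent(n: int, total: int) -> float:
    """Percentage 100*n/total rounded half away from zero to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= n <= total:
        raise ValueError("need 0 <= n <= total")
    tenths = Fraction(1000 * int(n), int(total))
    return math.floor(tenths + Fraction(1, 2)) / 10.0


def age_band(age_at_index: float) -> str:
    """Half-open age bands; ages below 4 should have been excluded upstream."""
    if age_at_index < 4:
        raise ValueError("age below cohort minimum of 4 years")
    if age_at_index < 12:
        return "child"
    if age_at_index < 18:
        return "adolescent"
    return "adult"


def saba_band(n_fills: int) -> str:
    if n_fills < 0:
        raise ValueError("negative fill count")
    if n_fills == 0:
        return "0"
    if n_fills <= 2:
        return "1-2"
    return ">=3"


def baseline_window(
    prescriptions: pd.DataFrame, index_date: pd.Timestamp, days: int = 365
) -> pd.DataFrame:
    """Prescriptions in the baseline window (index day itself excluded)."""
    d = prescriptions["date"]
    lo = index_date - pd.Timedelta(days=days)
    return prescriptions.loc[(d >= lo) & (d < index_date)]


def count_saba_fills(
    prescriptions: pd.DataFrame, index_date: pd.Timestamp, days: int = 365
) -> str:
    """SABA fill band over the 12 months before index."""
    base = baseline_window(prescriptions, index_date, days)
    return saba_band(int((base["therapy_class"] == "SABA").sum()))


# ---------------------------------------------------------------------------
# GINA 2020 step derivation

_ICS_EQ_CACHE: dict[str, float] | None = None


def _ics_equivalence() -> dict[str, float]:
    global _ICS_EQ_CACHE
    if _ICS_EQ_CACHE is None:
        ref = importlib.resources.files("ocspatterns.data") / "ics_equivalence.csv"
        df = pd.read_csv(str(ref))
        _ICS_EQ_CACHE = {
            str(s).lower(): float(f)
            for s, f in zip(df["substance"], df["bdp_equivalent_factor"])
        }
    return dict(_ICS_EQ_CACHE)


def ics_dose_band(drug: str, strength_mg_per_unit: float, instruction_text: str) -> str:
    """Classify an ICS-containing script as low/medium/high daily dose.

    The daily dose in beclometasone-equivalent ug is strength x units/day x
    equivalence factor; "unknown" when units/day cannot be parsed or the
    product is not in the equivalence table.
    """
    factors = _ics_equivalence()
    factor = factors.get(str(drug).lower())
    parsed = parse_dosage(instruction_text)
    if factor is None or parsed.units_per_day is None or pd.isna(strength_mg_per_unit):
        return "unknown"
    daily_ug = float(strength_mg_per_unit) * 1000.0 * parsed.units_per_day * factor
    if daily_ug <= ICS_LOW_MAX_UG:
        return "low"
    if daily_ug <= ICS_MEDIUM_MAX_UG:
        return "medium"
    return "high"


def _load_gina_rules(path=None) -> pd.DataFrame:
    if path is None:
        path = str(importlib.resources.files("ocspatterns.data") / "gina_step_rules.csv")
    return pd.read_csv(path, keep_default_na=False).sort_values("priority")


def assign_gina_step(
    baseline_rx: pd.DataFrame, rule_table: pd.DataFrame | None = None
) -> int:
    """Highest-matching GINA 2020 step (0 = no asthma medication) at baseline.

    Each rule names a therapy class, an ICS dose band ("any" matches every
    band) and optionally a co-required class; the first rule, in priority
    order, with a matching baseline record wins.  Records with therapy
    classes outside the known vocabulary are ignored with a warning.
    """
    rules = rule_table if rule_table is not None else _load_gina_rules()
    known = {"OCS", "SABA", "ICS", "ICS_LABA", "LTRA", "LAMA", "biologic", "other"}
    unknown = ~baseline_rx["therapy_class"].isin(known)
    if unknown.any():
        warnings.warn(f"ignoring {int(unknown.sum())} records with unknown therapy class")
        baseline_rx = baseline_rx.loc[~unknown]

    bands = {}
    for idx, row in baseline_rx.iterrows():
        if row["therapy_class"] in ("ICS", "ICS_LABA"):
            bands[idx] = ics_dose_band(row["drug"], row.get("strength_mg_per_unit"),
                                       row.get("instruction_text", ""))
    classes_present = set(baseline_rx["therapy_class"])
    for _, rule in rules.iterrows():
        cls = rule["therapy_class"]
        want_band = rule["dose_band"]
        requires = rule["requires_class"]
        hits = baseline_rx.loc[baseline_rx["therapy_class"] == cls]
        if want_band != "any":
            hits = hits.loc[[i for i in hits.index if bands.get(i) == want_band]]
        if hits.empty:
            continue
        if requires and requires not in classes_present:
            continue
        return int(rule["step"])
    return 0


# ---------------------------------------------------------------------------
# Pattern summary tables

_SEVERITY = {c: i for i, c in enumerate(GAP_CATEGORIES)}  # frequent = most severe


def _top_category(label: str) -> str | None:
    """Most severe (shortest-gap) category named by a detailed label."""
    low = label.lower()
    if low == "once-only":
        return None
    # strip longer words first: "infrequent"/"moderately frequent" contain "frequent"
    present = []
    rest = low
    if "moderately frequent" in rest:
        present.append("moderately_frequent")
        rest = rest.replace("moderately frequent", "")
    if "infrequent" in rest:
        present.append("infrequent")
        rest = rest.replace("infrequent", "")
    if "frequent" in rest:
        present.append("frequent")
    if "sporadic" in low:
        present.append("sporadic")
    return max(present, key=lambda c: _SEVERITY[c])


#: Table rows in canonical display order: leaves grouped under their super-row
TABLE_ORDER: list[tuple[str, str]] = [("Once-only", "leaf"), ("Sporadic", "leaf")]
for _super, _word in (("Any infrequent", "infrequent"),
                      ("Any moderately frequent", "moderately_frequent"),
                      ("Any frequent", "frequent")):
    TABLE_ORDER.append((_super, "super"))
    TABLE_ORDER.extend(
        (lab, "leaf") for lab in ALL_DETAILED_LABELS
        if lab != "Once-only" and _top_category(lab) == _word
    )
TABLE_ORDER.append(("Total", "total"))

_SUPER_MEMBERS = {
    sup: [lab for lab in ALL_DETAILED_LABELS
          if lab != "Once-only" and _top_category(lab) == word]
    for sup, word in (("Any infrequent", "infrequent"),
                      ("Any moderately frequent", "moderately_frequent"),
                      ("Any frequent", "frequent"))
}

_SINGLE_CATEGORY_LABELS = ("Once-only", "Sporadic", "Infrequent only",
                           "Moderately frequent only", "Frequent only")


def aggregate_detailed_counts(counts: Mapping[str, int]) -> dict[str, int]:
    """Aggregate per-detailed-label patient counts into the derived rows.

    Returns super-row counts ("Any infrequent/moderately frequent/frequent"),
    the Total, the single-category vs mixed split and the simplified
    three-way counts.  Input keys are detailed labels; missing labels count
    as zero.
    """
    get = lambda lab: int(counts.get(lab, 0))
    out = {sup: sum(get(lab) for lab in members)
           for sup, members in _SUPER_MEMBERS.items()}
    total = sum(get(lab) for lab in ALL_DETAILED_LABELS)
    out["Total"] = total
    single = sum(get(lab) for lab in _SINGLE_CATEGORY_LABELS)
    out["Single category"] = single
    out["Mixed patterns"] = total - single
    out["once_only"] = get("Once-only")
    out["frequent"] = out["Any frequent"]
    out["less_frequent"] = total - out["once_only"] - out["frequent"]
    return out


def summarize_patterns(profiles: pd.DataFrame) -> pd.DataFrame:
    """Detailed-pattern summary in the canonical table shape.

    ``profiles`` needs columns detailed_label and n_scripts (one row per
    patient).  Output rows follow TABLE_ORDER with n, percent of total and
    mean (SD) / median (IQR) prescriptions per patient.
    """
    total = len(profiles)
    groups = {lab: grp["n_scripts"].to_numpy()
              for lab, grp in profiles.groupby("detailed_label")}

    def row_values(label: str, kind: str) -> np.ndarray:
        if kind == "total":
            return profiles["n_scripts"].to_numpy()
        if kind == "super":
            members = _SUPER_MEMBERS[label]
            arrays = [groups[m] for m in members if m in groups]
            return np.concatenate(arrays) if arrays else np.array([])
        return groups.get(label, np.array([]))

    rows = []
    for label, kind in TABLE_ORDER:
        vals = row_values(label, kind)
        n = len(vals)
        rows.append({
            "label": label,
            "kind": kind,
            "n": n,
            "percent": percent(n, total) if total else float("nan"),
            "mean_rx": float(np.mean(vals)) if n else float("nan"),
            "sd_rx": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
            "median_rx": float(np.median(vals)) if n else float("nan"),
            "q1_rx": float(np.percentile(vals, 25)) if n else float("nan"),
            "q3_rx": float(np.percentile(vals, 75)) if n else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chi-square

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    pvalue: float
    table: pd.DataFrame
    column_percent: pd.DataFrame


def chisq_from_table(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Zero-margin rows/columns are dropped with a warning before testing.
    """
    tab = pd.DataFrame(table).astype(float)
    zero_rows = tab.sum(axis=1) == 0
    zero_cols = tab.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn(
            f"dropping {int(zero_rows.sum())} zero rows and "
            f"{int(zero_cols.sum())} zero columns from contingency table")
        tab = tab.loc[~zero_rows, ~zero_cols]
    stat, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    col_pct = tab.div(tab.sum(axis=0), axis=1) * 100.0
    return ChiSquareResult(statistic=float(stat), dof=int(dof), pvalue=float(p),
                           table=tab, column_percent=col_pct)


def crosstab_and_chisq(labels: pd.Series, stratifier: pd.Series) -> ChiSquareResult:
    """Cross-tabulate pattern labels against a stratifier and test association."""
    tab = pd.crosstab(labels, stratifier)
    return chisq_from_table(tab)


def load_published_pattern_table() -> pd.DataFrame:
    """Published detailed-pattern table (counts and printed statistics).

    Bundled as data so aggregation identities and percentage cells can be
    recomputed from the printed counts.
    """
    ref = importlib.resources.files("ocspatterns.data") / "published_pattern_table.csv"
    return pd.read_csv(str(ref))
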