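"""Domain types, table IO and dose standardization for EHR-style OCS records.

Three delimited tables describe a cohort: patients (demographics and
registration span), prescriptions (dated drug issues with free-text dosing
instructions) and clinical events (coded diagnoses/consultations).  All doses
are standardized to prednisolone-equivalent mg/day through the WHO ATC/DDD
defined daily dose of each oral corticosteroid substance, with prednisolone
(DDD 10 mg) as the anchor.
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PatientRecord",
    "PrescriptionRecord",
    "ClinicalEvent",
    "ParsedInstruction",
    "TableBundle",
    "THERAPY_CLASSES",
    "EVENT_CATEGORIES",
    "EXCLUSION_CONDITIONS",
    "load_ddd_table",
    "to_prednisolone_equivalent",
    "parse_dosage",
    "daily_dose_from_script",
    "read_tables",
    "write_tables",
]

THERAPY_CLASSES = frozenset(
    {"OCS", "SABA", "ICS", "ICS_LABA", "LTRA", "LAMA", "biologic", "other"}
)

#: chronic OCS-treated conditions that exclude adult patients
EXCLUSION_CONDITIONS = (
    "ankylosing_spondylitis",
    "sjogrens_syndrome",
    "systemic_lupus_erythematosus",
    "temporal_arteritis",
    "ulcerative_colitis",
    "psoriatic_arthritis",
    "multiple_sclerosis",
    "polymyalgia_rheumatica",
    "crohns_disease",
    "cancer_of_respiratory_system",
)

EVENT_CATEGORIES = frozenset(
    {"asthma_diagnosis", "asthma_consultation", "lrti", "exacerbation"}
    | {f"exclusion_condition:{c}" for c in EXCLUSION_CONDITIONS}
)

SEX_VALUES = frozenset({"male", "female", "unknown"})


class SchemaError(ValueError):
    """A mandatory column is missing or a table cannot be interpreted."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    birth_date: date
    registration_start: date
    registration_end: date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_VALUES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.birth_date > self.registration_start:
            raise ValueError("birth_date after registration_start")
        if self.registration_end is not None and self.registration_start > self.registration_end:
            raise ValueError("registration_start after registration_end")


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    date: date
    drug: str
    therapy_class: str
    strength_mg_per_unit: float | None = None
    quantity_units: float | None = None
    instruction_text: str = ""

    def __post_init__(self) -> None:
        if self.therapy_class not in THERAPY_CLASSES:
            raise ValueError(f"unknown therapy_class {self.therapy_class!r}")
        if self.strength_mg_per_unit is not None and self.strength_mg_per_unit < 0:
            raise ValueError("negative strength")
        if self.quantity_units is not None and self.quantity_units <= 0:
            raise ValueError("non-positive quantity")


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    date: date
    category: str

    def __post_init__(self) -> None:
        if self.category not in EVENT_CATEGORIES:
            raise ValueError(f"unknown event category {self.category!r}")


# ---------------------------------------------------------------------------
# DDD conversion

_DDD_CACHE: dict[str, float] | None = None


def load_ddd_table(path: str | Path | None = None) -> dict[str, float]:
    """Load the substance -> defined daily dose (mg) mapping.

    The bundled table covers the common oral H02AB corticosteroids; a custom
    table may be supplied as a CSV with columns ``substance`` and ``ddd_mg``.
    """
    global _DDD_CACHE
    if path is None and _DDD_CACHE is not None:
        return dict(_DDD_CACHE)
    if path is None:
        ref = importlib.resources.files("ocspatterns.data") / "ddd_h02ab.csv"
        df = pd.read_csv(str(ref))
    else:
        df = pd.read_csv(path)
    table = {str(s).strip().lower(): float(d) for s, d in zip(df["substance"], df["ddd_mg"])}
    if "prednisolone" not in table:
        raise SchemaError("DDD table must contain prednisolone (the equivalence anchor)")
    if any(v <= 0 for v in table.values()):
        raise ValueError("DDD values must be positive")
    if path is None:
        _DDD_CACHE = dict(table)
    return table


class UnknownSubstanceError(KeyError):
    """OCS substance absent from the DDD table."""


def to_prednisolone_equivalent(
    drug: str, daily_dose_mg: float, ddd_table: Mapping[str, float] | None = None
) -> float:
    """Convert a daily dose of an OCS substance to prednisolone-equivalent mg/day.

    The conversion scales by the ratio of defined daily doses:
    ``dose * DDD(prednisolone) / DDD(drug)``, so one DDD of any substance maps
    to one DDD (10 mg) of prednisolone.
    """
    if daily_dose_mg < 0:
        raise ValueError("daily_dose_mg must be nonnegative")
    table = ddd_table if ddd_table is not None else load_ddd_table()
    key = drug.strip().lower()
    if key not in table:
        raise UnknownSubstanceError(drug)
    return daily_dose_mg * table["prednisolone"] / table[key]


# ---------------------------------------------------------------------------
# Free-text dosing-instruction parsing (units/day and course duration)

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "fourteen": 14, "twenty": 20, "twenty-eight": 28,
}
_NUM = r"(\d+(?:\.\d+)?|" + "|".join(_NUMBER_WORDS) + r")"

_FREQ_WORDS = {"once": 1, "twice": 2, "three times": 3, "four times": 4}

_RE_UNITS = re.compile(
    _NUM + r"\s*(?:tablets?|tabs?|puffs?|capsules?)?\s*"
    r"(?:(once|twice|three times|four times)\s+(?:daily|a day|per day)"
    r"|daily|a day|per day|each day|every day|od\b)",
    re.IGNORECASE,
)
_RE_DURATION = re.compile(
    r"for\s+" + _NUM + r"\s+(days?|weeks?)", re.IGNORECASE
)


def _to_number(token: str) -> float:
    token = token.lower()
    if token in _NUMBER_WORDS:
        return float(_NUMBER_WORDS[token])
    return float(token)


@dataclass(frozen=True)
class ParsedInstruction:
    """Structured reading of a free-text dosing instruction."""

    units_per_day: float | None = None
    duration_days: float | None = None


def parse_dosage(text: str | None) -> ParsedInstruction:
    """Extract units/day and course duration from a dosing instruction.

    Rule-based: handles patterns like "take 8 tablets daily", "two puffs
    twice daily", "for 5 days".  Free text never raises; unmatched fields
    are returned as None.
    """
    if not text or not isinstance(text, str):
        return ParsedInstruction()
    units = None
    m = _RE_UNITS.search(text)
    if m:
        n = _to_number(m.group(1))
        mult = _FREQ_WORDS.get((m.group(2) or "").lower(), 1)
        units = n * mult
    duration = None
    m = _RE_DURATION.search(text)
    if m:
        duration = _to_number(m.group(1))
        if m.group(2).lower().startswith("week"):
            duration *= 7
    return ParsedInstruction(units_per_day=units, duration_days=duration)


def daily_dose_from_script(
    rx: PrescriptionRecord, parsed: ParsedInstruction | None = None
) -> float | None:
    """Best-available daily dose (mg/day of the prescribed substance).

    Preference order: units/day stated in the instruction, then quantity
    spread over a parsed course duration.  Returns None when neither route
    yields a dose.
    """
    if rx.therapy_class != "OCS":
        raise ValueError("daily dose is only defined for OCS scripts")
    if parsed is None:
        parsed = parse_dosage(rx.instruction_text)
    strength = rx.strength_mg_per_unit
    if strength is None:
        return None
    if parsed.units_per_day is not None:
        dose = strength * parsed.units_per_day
    elif rx.quantity_units is not None and parsed.duration_days:
        dose = strength * rx.quantity_units / parsed.duration_days
    else:
        return None
    if dose < 0:
        raise ValueError("negative daily dose")
    return dose


# ---------------------------------------------------------------------------
# Table IO

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "registration_start", "registration_end"]
PRESCRIPTION_COLUMNS = [
    "patient_id", "date", "drug", "therapy_class",
    "strength_mg_per_unit", "quantity_units", "instruction_text",
]
EVENT_COLUMNS = ["patient_id", "date", "category"]

_MANDATORY = {
    "patients": ["patient_id", "sex", "birth_date", "registration_start"],
    "prescriptions": ["patient_id", "date", "drug", "therapy_class"],
    "events": ["patient_id", "date", "category"],
}
_DATE_COLS = {
    "patients": ["birth_date", "registration_start", "registration_end"],
    "prescriptions": ["date"],
    "events": ["date"],
}
_OPTIONAL_DATE = {"registration_end"}


@dataclass
class TableBundle:
    """The three normalized input tables plus row-level rejects."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )


def _parse_dates(series: pd.Series, dayfirst: bool) -> pd.Series:
    if dayfirst:
        return pd.to_datetime(series, errors="coerce", dayfirst=True)
    return pd.to_datetime(series, errors="coerce", format="ISO8601")


def _read_one(
    path: str | Path,
    table: str,
    all_columns: Sequence[str],
    column_map: Mapping[str, str] | None,
    dayfirst: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    for col in _MANDATORY[table]:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing mandatory column {col!r}")
    for col in all_columns:
        if col not in df.columns:
            df[col] = ""
    df = df[list(all_columns)]
    df.index.name = "row"

    bad = pd.Series(pd.NA, index=df.index, dtype="string")
    for col in _DATE_COLS[table]:
        raw = df[col].replace("", pd.NA)
        parsed = _parse_dates(raw, dayfirst)
        missing_ok = col in _OPTIONAL_DATE
        invalid = parsed.isna() & (raw.notna() if missing_ok else True)
        bad = bad.fillna(pd.Series(np.where(invalid, f"unparseable date in {col}", pd.NA),
                                   index=df.index, dtype="string"))
        df[col] = parsed
    for col in ("strength_mg_per_unit", "quantity_units"):
        if col in df.columns:
            raw = df[col].replace("", pd.NA)
            num = pd.to_numeric(raw, errors="coerce")
            invalid = num.isna() & raw.notna()
            bad = bad.fillna(pd.Series(np.where(invalid, f"non-numeric {col}", pd.NA),
                                       index=df.index, dtype="string"))
            df[col] = num
    if "therapy_class" in df.columns:
        unknown = ~df["therapy_class"].isin(THERAPY_CLASSES)
        bad = bad.fillna(pd.Series(np.where(unknown, "unknown therapy_class", pd.NA),
                                   index=df.index, dtype="string"))
    if "category" in df.columns:
        unknown = ~df["category"].isin(EVENT_CATEGORIES)
        bad = bad.fillna(pd.Series(np.where(unknown, "unknown event category", pd.NA),
                                   index=df.index, dtype="string"))

    rejects = df.loc[bad.notna()].copy()
    rejects_report = pd.DataFrame(
        {"table": table, "row": rejects.index, "reason": bad.loc[bad.notna()].to_numpy()}
    )
    accepted = df.loc[bad.isna()].reset_index(drop=True)
    return accepted, rejects_report


def read_tables(
    patients_path: str | Path,
    prescriptions_path: str | Path,
    events_path: str | Path,
    schema_config: Mapping[str, Mapping[str, str]] | None = None,
    dayfirst: bool = False,
) -> TableBundle:
    """Read and normalize the three input CSVs.

    ``schema_config`` maps, per table, canonical column names to source
    column names.  Rows that fail type coercion are collected into the
    bundle's rejects report rather than dropped silently; a missing
    mandatory column raises :class:`SchemaError`.
    """
    cfg = schema_config or {}
    patients, rej_p = _read_one(patients_path, "patients", PATIENT_COLUMNS,
                                cfg.get("patients"), dayfirst)
    rx, rej_rx = _read_one(prescriptions_path, "prescriptions", PRESCRIPTION_COLUMNS,
                           cfg.get("prescriptions"), dayfirst)
    events, rej_ev = _read_one(events_path, "events", EVENT_COLUMNS,
                               cfg.get("events"), dayfirst)
    rejects = pd.concat([rej_p, rej_rx, rej_ev], ignore_index=True)
    return TableBundle(patients=patients, prescriptions=rx, events=events, rejects=rejects)


def write_tables(bundle: TableBundle, outdir: str | Path) -> dict[str, Path]:
    """Write normalized tables (and the rejects report) as CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("patients", bundle.patients),
        ("prescriptions", bundle.prescriptions),
        ("events", bundle.events),
        ("rejects", bundle.rejects),
    ):
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths
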