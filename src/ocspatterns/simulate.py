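"""Synthetic EHR cohort generator with known ground truth.

Emits the three input tables (patients, prescriptions, events) plus a
ground-truth table recording each patient's intended eligibility, study
arm, script labels, gap-pattern profile and baseline stratifiers, so the
whole pipeline can be validated end to end without access-restricted data.

In strict mode (default) gaps are sampled strictly inside their category
intervals (at least one day away from every boundary) and every script
carries a feature that is decisive at a known algorithm step, so pipeline
recovery of the ground truth is exact by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_model import EXCLUSION_CONDITIONS
from .patterns import GAP_CATEGORIES, derive_profile

__all__ = ["SimulationConfig", "SimBundle", "generate", "make_boundary_fixtures"]

_STRICT_GAP_RANGES = {
    "frequent": (10, 88),
    "moderately_frequent": (91, 180),
    "infrequent": (183, 363),
    "sporadic": (366, 500),
}
_LOOSE_GAP_RANGES = {
    "frequent": (1, 89),
    "moderately_frequent": (90, 181),
    "infrequent": (182, 364),
    "sporadic": (365, 500),
}

#: default mixture over pattern ground truths for eligible intermittent-only
#: patients, echoing the published distribution of use patterns
DEFAULT_PATTERN_MIXTURE: Mapping[str, float] = {
    "once_only": 0.42,
    "sporadic": 0.14,
    "infrequent": 0.07,
    "moderately_frequent": 0.06,
    "frequent": 0.19,
    "mixed:sporadic+frequent": 0.12,
}

DEFAULT_INELIGIBLE_FRACTIONS: Mapping[str, float] = {
    "age_below_minimum": 0.02,
    "no_concurrent_asthma_event": 0.02,
    "insufficient_baseline": 0.02,
    "exclusion_condition": 0.02,
}

# therapy bundles realizing each GINA step target (drug, class, strength mg,
# instruction); ICS doses chosen to land deterministically in a dose band
_STEP_MEDS = {
    1: [],
    2: [("beclometasone", "ICS", 0.1, "two puffs twice daily")],
    3: [("fluticasone_propionate", "ICS_LABA", 0.05, "two puffs twice daily")],
    4: [("beclometasone", "ICS_LABA", 0.2, "two puffs twice daily")],
    5: [("beclometasone", "ICS_LABA", 0.25, "two puffs twice daily"),
        ("omalizumab", "biologic", 75.0, "")],
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; the seed fully determines the output."""

    n_patients: int = 200
    seed: int = 0
    pattern_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIXTURE))
    strict_gaps: bool = True
    frac_long_term: float = 0.05
    frac_non_ocs: float = 0.05
    ineligible_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INELIGIBLE_FRACTIONS))
    age_band_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"child": 0.16, "adolescent": 0.08, "adult": 0.76})
    gina_step_mixture: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.138, 1: 0.251, 2: 0.320, 3: 0.184,
                                 4: 0.087, 5: 0.020})
    saba_band_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"0": 0.238, "1-2": 0.449, ">=3": 0.313})
    decisive_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"instruction": 0.4, "dose": 0.4,
                                 "concurrent_event": 0.2})
    #: optional per-pattern (min, max) total script counts
    scripts_per_pattern: Mapping[str, tuple[int, int]] | None = None
    max_extra_gaps: int = 2

    def validate(self) -> None:
        for name, mix in (("pattern_mixture", self.pattern_mixture),
                          ("age_band_mixture", self.age_band_mixture),
                          ("gina_step_mixture", self.gina_step_mixture),
                          ("saba_band_mixture", self.saba_band_mixture),
                          ("decisive_mixture", self.decisive_mixture)):
            vals = list(mix.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        for key in self.pattern_mixture:
            _required_categories(key)  # raises on unknown pattern
        if self.scripts_per_pattern:
            for key, (lo, hi) in self.scripts_per_pattern.items():
                need = len(_required_categories(key)) + 1 if key != "once_only" else 1
                if lo > hi or lo < need:
                    raise ValueError(
                        f"pattern {key!r} needs >= {need} scripts, got range ({lo}, {hi})")
        frac = (self.frac_long_term + self.frac_non_ocs
                + sum(self.ineligible_fractions.values()))
        if frac >= 1.0:
            raise ValueError("planted-role fractions leave no eligible patients")


def _required_categories(pattern: str) -> list[str]:
    if pattern == "once_only":
        return []
    if pattern in GAP_CATEGORIES:
        return [pattern]
    if pattern.startswith("mixed:"):
        cats = pattern[len("mixed:"):].split("+")
        bad = [c for c in cats if c not in GAP_CATEGORIES]
        if bad or len(set(cats)) < 2:
            raise ValueError(f"invalid mixed pattern {pattern!r}")
        return list(dict.fromkeys(cats))
    raise ValueError(f"unknown pattern {pattern!r}")


@dataclass
class SimBundle:
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    ground_truth: pd.DataFrame


_AGE_RANGES = {"child": (4, 11), "adolescent": (12, 17), "adult": (18, 75)}


class _Builder:
    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.patients: list[dict] = []
        self.rx: list[dict] = []
        self.events: list[dict] = []
        self.truth: list[dict] = []
        self.gap_ranges = (_STRICT_GAP_RANGES if config.strict_gaps
                           else _LOOSE_GAP_RANGES)
        self._excl_cycle = 0

    # -- small samplers ----------------------------------------------------
    def _choice(self, mixture: Mapping) -> object:
        keys = list(mixture.keys())
        probs = np.array([mixture[k] for k in keys], dtype=float)
        return keys[self.rng.choice(len(keys), p=probs / probs.sum())]

    def _days(self, lo: int, hi: int) -> pd.Timedelta:
        return pd.Timedelta(days=int(self.rng.integers(lo, hi + 1)))

    # -- patient roles -----------------------------------------------------
    def _roles(self) -> list[str]:
        cfg = self.cfg
        roles, probs = ["eligible"], []
        p_special = []
        for reason, frac in cfg.ineligible_fractions.items():
            roles.append(f"ineligible:{reason}")
            p_special.append(frac)
        roles.append("long_term")
        p_special.append(cfg.frac_long_term)
        roles.append("non_ocs")
        p_special.append(cfg.frac_non_ocs)
        probs = [1.0 - sum(p_special)] + p_special
        idx = self.rng.choice(len(roles), size=cfg.n_patients, p=probs)
        return [roles[i] for i in idx]

    # -- one patient -------------------------------------------------------
    def add_patient(self, i: int, role: str) -> None:
        cfg, rng = self.cfg, self.rng
        pid = f"P{i:05d}"
        index = pd.Timestamp("2012-01-01") + self._days(0, 1460)

        if role == "ineligible:age_below_minimum":
            age = int(rng.integers(1, 4))
            band = "child"
        elif role == "ineligible:exclusion_condition":
            band = "adult"
            age = int(rng.integers(*_AGE_RANGES[band]))
        else:
            band = self._choice(cfg.age_band_mixture)
            age = int(rng.integers(_AGE_RANGES[band][0], _AGE_RANGES[band][1] + 1))
        birth = index - pd.DateOffset(years=age) - self._days(30, 330)

        if role == "ineligible:insufficient_baseline":
            reg_start = index - self._days(30, 300)
        else:
            reg_start = index - pd.Timedelta(days=365) - self._days(30, 2000)
        if reg_start < birth:
            reg_start = birth

        # asthma event concurrent with index (or deliberately distant)
        if role == "ineligible:no_concurrent_asthma_event":
            self.events.append({"patient_id": pid, "date": index + pd.Timedelta(days=200),
                                "category": "asthma_diagnosis"})
        else:
            self.events.append({"patient_id": pid, "date": index + self._days(-60, 60),
                                "category": "asthma_diagnosis"})

        gina_step, saba = 0, "0"
        if role in ("eligible", "long_term", "non_ocs"):
            gina_step, saba = self._baseline_therapy(pid, index)

        pattern, detailed, simplified, n_scripts, use = "", "", "", 0, ""
        exclusion_reason = ""
        arm = "ocs"
        if role == "eligible":
            pattern = self._choice(cfg.pattern_mixture)
            dates = self._course_dates(pattern, index)
            for d in dates:
                self._add_ocs_script(pid, d, intermittent=True)
            profile = derive_profile(dates)
            detailed, simplified = profile.detailed_label, profile.simplified_label
            n_scripts, use = len(dates), "intermittent_only"
            eligible = True
        elif role == "long_term":
            n = int(rng.integers(1, 4))
            dates = [index + pd.Timedelta(days=120 * k) for k in range(n)]
            for k, d in enumerate(dates):
                self._add_ocs_script(pid, d, intermittent=(k > 0))
            n_scripts, use = n, "any_long_term"
            eligible = True
        elif role == "non_ocs":
            arm = "non_ocs"
            # reference date for arm without OCS; re-anchor birth to keep the
            # intended age at that date
            index = reg_start + pd.Timedelta(days=365)
            birth = index - pd.DateOffset(years=age) - self._days(30, 330)
            self.events.append({"patient_id": pid, "date": index + self._days(-60, 60),
                                "category": "asthma_diagnosis"})
            eligible = True
        elif role == "ineligible:exclusion_condition":
            cond = EXCLUSION_CONDITIONS[self._excl_cycle % len(EXCLUSION_CONDITIONS)]
            self._excl_cycle += 1
            self.events.append({"patient_id": pid, "date": index - self._days(100, 2000),
                                "category": f"exclusion_condition:{cond}"})
            self._add_ocs_script(pid, index, intermittent=True)
            eligible = False
            exclusion_reason = f"exclusion_condition:{cond}"
        else:  # age / no event / baseline violations: one plain OCS script
            self._add_ocs_script(pid, index, intermittent=True)
            eligible = False
            exclusion_reason = role.split(":", 1)[1]

        last = index + pd.Timedelta(days=4000)
        self.patients.append({
            "patient_id": pid,
            "sex": "male" if rng.random() < 0.45 else "female",
            "birth_date": birth,
            "registration_start": reg_start,
            "registration_end": last,
        })
        self.truth.append({
            "patient_id": pid, "role": role, "arm": arm, "eligible": eligible,
            "exclusion_reason": exclusion_reason, "index_date": index,
            "age_at_index": age,
            "age_band": band, "gina_step": gina_step, "saba_band": saba,
            "pattern": pattern, "detailed_label": detailed,
            "simplified_label": simplified, "n_ocs_scripts": n_scripts,
            "patient_use": use,
        })

    def _course_dates(self, pattern: str, index: pd.Timestamp) -> list[pd.Timestamp]:
        cfg, rng = self.cfg, self.rng
        required = _required_categories(pattern)
        if pattern == "once_only":
            return [index]
        if cfg.scripts_per_pattern and pattern in cfg.scripts_per_pattern:
            lo, hi = cfg.scripts_per_pattern[pattern]
            n_gaps = int(rng.integers(lo, hi + 1)) - 1
        else:
            n_gaps = len(required) + int(rng.integers(0, cfg.max_extra_gaps + 1))
        cats = list(required)
        while len(cats) < n_gaps:
            cats.append(required[int(rng.integers(0, len(required)))])
        rng.shuffle(cats)
        dates, current = [index], index
        for c in cats:
            lo, hi = self.gap_ranges[c]
            current = current + self._days(lo, hi)
            dates.append(current)
        return dates

    def _add_ocs_script(self, pid: str, date: pd.Timestamp, intermittent: bool) -> None:
        rng = self.rng
        if not intermittent:
            self.rx.append({
                "patient_id": pid, "date": date, "drug": "prednisolone",
                "therapy_class": "OCS", "strength_mg_per_unit": 5.0,
                "quantity_units": 28.0,
                "instruction_text": "one tablet daily long term",
            })
            return
        mech = self._choice(self.cfg.decisive_mixture)
        if mech == "instruction":
            self.rx.append({
                "patient_id": pid, "date": date, "drug": "prednisolone",
                "therapy_class": "OCS", "strength_mg_per_unit": 5.0,
                "quantity_units": 40.0,
                "instruction_text": "take eight tablets daily for 5 days then stop",
            })
        elif mech == "dose":
            if rng.random() < 0.5:
                drug, strength, instr = "prednisolone", 5.0, "8 tablets daily"
            else:
                drug, strength, instr = "dexamethasone", 2.0, "4 tablets daily"
            self.rx.append({
                "patient_id": pid, "date": date, "drug": drug,
                "therapy_class": "OCS", "strength_mg_per_unit": strength,
                "quantity_units": np.nan, "instruction_text": instr,
            })
        else:  # concurrent LRTI/exacerbation, dose unknowable
            self.rx.append({
                "patient_id": pid, "date": date, "drug": "prednisolone",
                "therapy_class": "OCS", "strength_mg_per_unit": 5.0,
                "quantity_units": np.nan, "instruction_text": "as directed",
            })
            cat = "exacerbation" if rng.random() < 0.5 else "lrti"
            self.events.append({"patient_id": pid,
                                "date": date + self._days(-3, 3), "category": cat})

    def _baseline_therapy(self, pid: str, index: pd.Timestamp) -> tuple[int, str]:
        cfg, rng = self.cfg, self.rng
        step = int(self._choice(cfg.gina_step_mixture))
        band = self._choice(cfg.saba_band_mixture)
        n_saba = {"0": 0, "1-2": int(rng.integers(1, 3)),
                  ">=3": int(rng.integers(3, 7))}[band]
        if step == 1 and n_saba == 0:
            n_saba, band = 1, "1-2"
        if step == 0:
            n_saba, band = 0, "0"
        for _ in range(n_saba):
            self.rx.append({
                "patient_id": pid, "date": index - self._days(10, 350),
                "drug": "salbutamol", "therapy_class": "SABA",
                "strength_mg_per_unit": 0.1, "quantity_units": 200.0,
                "instruction_text": "two puffs when required",
            })
        for drug, cls, strength, instr in _STEP_MEDS.get(step, []):
            self.rx.append({
                "patient_id": pid, "date": index - self._days(10, 350),
                "drug": drug, "therapy_class": cls,
                "strength_mg_per_unit": strength, "quantity_units": 1.0,
                "instruction_text": instr,
            })
        return step, band

    # -- assembly ----------------------------------------------------------
    def build(self) -> SimBundle:
        for i, role in enumerate(self._roles()):
            self.add_patient(i, role)
        patients = pd.DataFrame(self.patients)
        rx = pd.DataFrame(self.rx, columns=[
            "patient_id", "date", "drug", "therapy_class",
            "strength_mg_per_unit", "quantity_units", "instruction_text"])
        events = pd.DataFrame(self.events, columns=["patient_id", "date", "category"])
        truth = pd.DataFrame(self.truth)
        return SimBundle(patients=patients, prescriptions=rx,
                         events=events, ground_truth=truth)


def generate(config: SimulationConfig | None = None) -> SimBundle:
    """Generate a synthetic cohort; identical config -> identical output."""
    return _Builder(config or SimulationConfig()).build()


def make_boundary_fixtures() -> SimBundle:
    """Small hand-written cohort exercising every rule boundary.

    Covers gaps of 89/90/181/182/364/365 days, same-day duplicate scripts,
    ages 3/4/11/12/17/18 at index, an asthma event exactly at the
    concurrency-window edge, each exclusion condition once (adults) and a
    minor whose exclusion-condition diagnosis is not concurrent with OCS.
    """
    patients, rx, events, truth = [], [], [], []
    index = pd.Timestamp("2012-06-01")

    def add(pid, age_years, reg_years_before=5):
        patients.append({
            "patient_id": pid, "sex": "female",
            "birth_date": index - pd.DateOffset(years=age_years, days=100),
            "registration_start": index - pd.DateOffset(years=reg_years_before),
            "registration_end": index + pd.DateOffset(years=8),
        })
        events.append({"patient_id": pid, "date": index, "category": "asthma_diagnosis"})

    def script(pid, date):
        rx.append({"patient_id": pid, "date": date, "drug": "prednisolone",
                   "therapy_class": "OCS", "strength_mg_per_unit": 5.0,
                   "quantity_units": 40.0,
                   "instruction_text": "take eight tablets daily for 5 days then stop"})

    gap_expect = [(89, "frequent"), (90, "moderately_frequent"),
                  (181, "moderately_frequent"), (182, "infrequent"),
                  (364, "infrequent"), (365, "sporadic")]
    for gap, cat in gap_expect:
        pid = f"GAP{gap:03d}"
        add(pid, 30)
        script(pid, index)
        script(pid, index + pd.Timedelta(days=gap))
        truth.append({"patient_id": pid, "expect": f"gap_category:{cat}"})

    add("DUP", 30)
    script("DUP", index)
    script("DUP", index)
    script("DUP", index + pd.Timedelta(days=100))
    truth.append({"patient_id": "DUP", "expect": "n_courses:2"})

    for age in (3, 4, 11, 12, 17, 18):
        pid = f"AGE{age:02d}"
        add(pid, age)
        script(pid, index)
        expect = ("ineligible:age_below_minimum" if age < 4 else
                  "age_band:" + ("child" if age < 12 else
                                 "adolescent" if age < 18 else "adult"))
        truth.append({"patient_id": pid, "expect": expect})

    # asthma event exactly at the 91-day window edge (eligible)
    patients.append({
        "patient_id": "EDGE", "sex": "male",
        "birth_date": index - pd.DateOffset(years=30, days=100),
        "registration_start": index - pd.DateOffset(years=5),
        "registration_end": index + pd.DateOffset(years=8)})
    events.append({"patient_id": "EDGE", "date": index + pd.Timedelta(days=91),
                   "category": "asthma_diagnosis"})
    script("EDGE", index)
    truth.append({"patient_id": "EDGE", "expect": "eligible:true"})

    for k, cond in enumerate(EXCLUSION_CONDITIONS):
        pid = f"EXC{k:02d}"
        add(pid, 40)
        script(pid, index)
        events.append({"patient_id": pid, "date": index - pd.Timedelta(days=800),
                       "category": f"exclusion_condition:{cond}"})
        truth.append({"patient_id": pid,
                      "expect": f"excluded:exclusion_condition:{cond}"})

    add("MINOR", 10)
    script("MINOR", index)
    events.append({"patient_id": "MINOR", "date": index - pd.Timedelta(days=3 * 365),
                   "category": "exclusion_condition:ulcerative_colitis"})
    truth.append({"patient_id": "MINOR", "expect": "eligible:true"})

    return SimBundle(
        patients=pd.DataFrame(patients),
        prescriptions=pd.DataFrame(rx),
        events=pd.DataFrame(events),
        ground_truth=pd.DataFrame(truth),
    )
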