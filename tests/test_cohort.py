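"""Inclusion/exclusion rules, index dates and the attrition log."""
import numpy as np
import pandas as pd
import pytest

from ocspatterns import cohort as cb
from ocspatterns import simulate


def _rx(pid, dates, cls="OCS"):
    return pd.DataFrame({
        "patient_id": pid, "date": [pd.Timestamp(d) for d in dates],
        "drug": "prednisolone", "therapy_class": cls,
        "strength_mg_per_unit": 5.0, "quantity_units": np.nan,
        "instruction_text": "",
    })


def _events(pid, dates, category="asthma_diagnosis"):
    return pd.DataFrame({"patient_id": pid,
                         "date": [pd.Timestamp(d) for d in dates],
                         "category": category})


class TestIndexDate:
    def test_earliest_ocs_script(self):
        rx = _rx("p", ["2010-06-01", "2010-05-01"])
        assert cb.find_index_date(rx) == pd.Timestamp("2010-05-01")

    def test_none_without_ocs(self):
        assert cb.find_index_date(_rx("p", ["2010-05-01"], cls="SABA")) is None

    def test_single_script_identity(self):
        rx = _rx("p", ["2011-03-02"])
        assert cb.find_index_date(rx) == pd.Timestamp("2011-03-02")


class TestInclusion:
    patient = pd.Series({"birth_date": pd.Timestamp("1980-01-01"),
                         "registration_start": pd.Timestamp("2008-01-01")})
    index = pd.Timestamp("2010-05-01")

    def test_eligible_patient(self):
        ok, reason = cb.check_inclusion(
            self.patient, self.index, _events("p", ["2010-05-11"]), _rx("p", []))
        assert ok and reason is None

    def test_age_below_four_fails_first(self):
        child = self.patient.copy()
        child["birth_date"] = pd.Timestamp("2007-06-01")
        ok, reason = cb.check_inclusion(
            child, self.index, _events("p", ["2010-05-11"]), _rx("p", []))
        assert not ok and reason == "age_below_minimum"

    def test_distant_asthma_event_fails(self):
        ok, reason = cb.check_inclusion(
            self.patient, self.index, _events("p", ["2010-11-17"]), _rx("p", []))
        assert not ok and reason == "no_concurrent_asthma_event"

    def test_asthma_medication_counts_as_event(self):
        saba = _rx("p", ["2010-04-20"], cls="SABA")
        ok, _ = cb.check_inclusion(self.patient, self.index,
                                   _events("p", [])[0:0], saba)
        assert ok

    def test_short_baseline_fails(self):
        late = self.patient.copy()
        late["registration_start"] = pd.Timestamp("2010-01-01")
        ok, reason = cb.check_inclusion(
            late, self.index, _events("p", ["2010-05-11"]), _rx("p", []))
        assert not ok and reason == "insufficient_baseline"


class TestExclusionConditions:
    def test_adult_with_condition_ever_excluded(self):
        ev = _events("p", ["2005-01-01"], "exclusion_condition:crohns_disease")
        excluded, cond = cb.check_exclusion_conditions(ev, _rx("p", []), 40)
        assert excluded and cond == "crohns_disease"

    def test_minor_nonconcurrent_condition_kept(self):
        ev = _events("p", ["2007-01-01"], "exclusion_condition:ulcerative_colitis")
        rx = _rx("p", ["2010-05-01"])
        excluded, _ = cb.check_exclusion_conditions(ev, rx, 10)
        assert not excluded

    def test_minor_concurrent_condition_excluded(self):
        ev = _events("p", ["2010-05-10"], "exclusion_condition:ulcerative_colitis")
        rx = _rx("p", ["2010-05-01"])
        excluded, cond = cb.check_exclusion_conditions(ev, rx, 10)
        assert excluded and cond == "ulcerative_colitis"

    def test_adult_without_condition_kept(self):
        excluded, _ = cb.check_exclusion_conditions(
            _events("p", [])[0:0], _rx("p", []), 40)
        assert not excluded


class TestBuildCohort:
    def test_planted_violations_reported(self, sim_bundle):
        cohort_df, attrition = cb.build_cohort(
            sim_bundle.patients, sim_bundle.prescriptions, sim_bundle.events)
        merged = cohort_df.merge(sim_bundle.ground_truth, on="patient_id",
                                 suffixes=("", "_gt"))
        assert (merged["eligible"] == merged["eligible_gt"]).all()
        planted = merged.loc[~merged["eligible_gt"]]
        assert (planted["exclusion_reason"] == planted["exclusion_reason_gt"]).all()

    def test_conservation(self, sim_bundle):
        cohort_df, attrition = cb.build_cohort(
            sim_bundle.patients, sim_bundle.prescriptions, sim_bundle.events)
        removed = attrition.loc[attrition["rule"] != "eligible", "n_removed"].sum()
        assert removed + cohort_df["eligible"].sum() == len(sim_bundle.patients)

    def test_empty_input(self):
        empty_p = pd.DataFrame(columns=["patient_id", "sex", "birth_date",
                                        "registration_start", "registration_end"])
        cohort_df, attrition = cb.build_cohort(empty_p, _rx("p", [])[0:0],
                                               _events("p", [])[0:0])
        assert cohort_df.empty
        assert (attrition["n_removed"] == 0).all()

    def test_order_invariance(self, sim_bundle):
        base, _ = cb.build_cohort(sim_bundle.patients, sim_bundle.prescriptions,
                                  sim_bundle.events)
        rng = np.random.default_rng(0)
        shuffled, _ = cb.build_cohort(
            sim_bundle.patients.sample(frac=1, random_state=1),
            sim_bundle.prescriptions.sample(frac=1, random_state=2),
            sim_bundle.events.sample(frac=1, random_state=3))
        a = base.sort_values("patient_id").reset_index(drop=True)
        b = shuffled.sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_series_equal(a["eligible"], b["eligible"])

    def test_monotonicity_removing_exclusion_diagnoses(self, sim_bundle):
        ev = sim_bundle.events
        stripped = ev.loc[~ev["category"].str.startswith("exclusion_condition:")]
        before, _ = cb.build_cohort(sim_bundle.patients, sim_bundle.prescriptions, ev)
        after, _ = cb.build_cohort(sim_bundle.patients, sim_bundle.prescriptions,
                                   stripped)
        m = before.merge(after, on="patient_id", suffixes=("_b", "_a"))
        assert not (m["eligible_b"] & ~m["eligible_a"]).any()

    def test_duplicate_patient_id_raises(self, sim_bundle):
        dup = pd.concat([sim_bundle.patients, sim_bundle.patients.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            cb.build_cohort(dup, sim_bundle.prescriptions, sim_bundle.events)


def test_age_at_handles_birthday_boundary():
    assert cb.age_at(pd.Timestamp("2000-06-15"), pd.Timestamp("2018-06-14")) == 17
    assert cb.age_at(pd.Timestamp("2000-06-15"), pd.Timestamp("2018-06-15")) == 18
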