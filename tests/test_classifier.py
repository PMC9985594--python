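"""The stepwise intermittent/long-term classification algorithm."""
import numpy as np
import pandas as pd
import pytest

from ocspatterns import classifier as cl


RULEBOOK = cl.load_rulebook()
CFG = cl.ClassifierConfig()


def _ocs(dates, instruction="", strength=5.0, quantity=np.nan, drug="prednisolone"):
    return pd.DataFrame({
        "patient_id": "p", "date": [pd.Timestamp(d) for d in dates],
        "drug": drug, "therapy_class": "OCS",
        "strength_mg_per_unit": strength, "quantity_units": quantity,
        "instruction_text": instruction,
    })


def _events(dates, category="exacerbation"):
    return pd.DataFrame({"patient_id": "p",
                         "date": [pd.Timestamp(d) for d in dates],
                         "category": category})


NO_EVENTS = _events([])[0:0]


@pytest.mark.parametrize("text,verdict", [
    ("take six tablets daily for 5 days then stop", "intermittent"),
    ("one daily long term", "long_term"),
    ("reducing course", "intermittent"),
    ("repeat dispensing", "long_term"),
    ("", "undecided"),
    ("with food", "undecided"),
])
def test_parse_instruction_rulebook(text, verdict):
    assert cl.parse_instruction(text, RULEBOOK) == verdict


@pytest.mark.parametrize("dose,verdict", [
    (40, "intermittent"),
    (20, "intermittent"),   # at-or-above high threshold
    (15, "undecided"),
    (10, "long_term"),      # at-or-below low threshold
    (5, "long_term"),
])
def test_classify_by_dose_thresholds(dose, verdict):
    assert cl.classify_by_dose(dose, CFG) == verdict


def test_classify_by_dose_rejects_negative():
    with pytest.raises(ValueError):
        cl.classify_by_dose(-1, CFG)


class TestConcurrentEvent:
    def test_event_inside_window(self):
        ev = _events(["2012-01-07"])
        assert cl.classify_by_concurrent_event(
            pd.Timestamp("2012-01-10"), ev, 14) == "intermittent"

    def test_event_outside_window(self):
        ev = _events(["2012-03-10"], category="lrti")
        assert cl.classify_by_concurrent_event(
            pd.Timestamp("2012-01-10"), ev, 14) == "undecided"

    def test_no_events(self):
        assert cl.classify_by_concurrent_event(
            pd.Timestamp("2012-01-10"), NO_EVENTS, 14) == "undecided"


class TestAnnualCount:
    def test_single_script_intermittent(self):
        labels = cl.classify_by_annual_count([pd.Timestamp("2012-01-01")], CFG)
        assert labels == ["intermittent"]

    def test_dense_scripts_become_long_term(self):
        # six undecided scripts inside one year: the third and later exceed
        # the annual maximum of two
        dates = [pd.Timestamp("2012-01-01") + pd.Timedelta(days=50 * k)
                 for k in range(6)]
        labels = cl.classify_by_annual_count(dates, CFG)
        assert labels == ["intermittent"] * 2 + ["long_term"] * 4

    def test_window_rolls(self):
        # two scripts a year apart never exceed the annual maximum
        dates = [pd.Timestamp("2012-01-01"), pd.Timestamp("2013-06-01"),
                 pd.Timestamp("2015-01-01")]
        assert cl.classify_by_annual_count(dates, CFG) == ["intermittent"] * 3

    def test_empty_input(self):
        assert cl.classify_by_annual_count([], CFG) == []


class TestClassifyPatient:
    def test_taper_instructions_decide_first(self):
        rx = _ocs(["2012-01-01", "2012-06-01", "2013-01-01"],
                  instruction="take six tablets daily for 5 days then stop")
        scripts, use = cl.classify_patient(rx, NO_EVENTS)
        assert (scripts["label"] == "intermittent").all()
        assert (scripts["decision_step"] == "instruction").all()
        assert use == "intermittent_only"

    def test_maintenance_plus_burst_is_any_long_term(self):
        low = _ocs(["2012-01-01"], instruction="1 tablet daily")    # 5 mg/day
        high = _ocs(["2012-06-01"], instruction="8 tablets daily")  # 40 mg/day
        scripts, use = cl.classify_patient(pd.concat([low, high]), NO_EVENTS)
        assert list(scripts["label"]) == ["long_term", "intermittent"]
        assert (scripts["decision_step"] == "dose").all()
        assert use == "any_long_term"

    def test_dose_conversion_between_substances(self):
        # 4 x 2 mg dexamethasone = 8 mg/day -> 53.3 mg/day prednisolone-eq
        rx = _ocs(["2012-01-01"], instruction="4 tablets daily",
                  strength=2.0, drug="dexamethasone")
        scripts, _ = cl.classify_patient(rx, NO_EVENTS)
        assert scripts.iloc[0]["label"] == "intermittent"
        assert scripts.iloc[0]["pred_equiv_mg_per_day"] == pytest.approx(8 * 10 / 1.5)

    def test_unknown_substance_falls_through_dose_step(self):
        rx = _ocs(["2012-01-01"], instruction="8 tablets daily", drug="mystery")
        ev = _events(["2012-01-03"])
        scripts, _ = cl.classify_patient(rx, ev)
        assert scripts.iloc[0]["decision_step"] == "concurrent_event"
        assert scripts.iloc[0]["label"] == "intermittent"

    def test_zero_scripts_is_an_error(self):
        with pytest.raises(ValueError):
            cl.classify_patient(_ocs([]), NO_EVENTS)

    def test_step_provenance_is_first_decisive(self):
        # instruction undecided, dose known but mid-range, concurrent event
        rx = _ocs(["2012-01-01"], instruction="3 tablets daily")  # 15 mg/day
        ev = _events(["2012-01-05"], category="lrti")
        scripts, _ = cl.classify_patient(rx, ev)
        assert scripts.iloc[0]["decision_step"] == "concurrent_event"

    def test_annual_count_is_last_resort(self):
        rx = _ocs(["2012-01-01"], instruction="as directed")
        scripts, _ = cl.classify_patient(rx, NO_EVENTS)
        assert scripts.iloc[0]["decision_step"] == "annual_count"
        assert scripts.iloc[0]["label"] == "intermittent"


def test_earlier_steps_shadow_dose_threshold_changes():
    """Tightening the dose thresholds cannot flip instruction-step labels."""
    rx = _ocs(["2012-01-01"], instruction="take 2 tablets daily for 7 days then stop")
    base, _ = cl.classify_patient(rx, NO_EVENTS, cl.ClassifierConfig())
    tight, _ = cl.classify_patient(
        rx, NO_EVENTS, cl.ClassifierConfig(dose_high_threshold_mg=100.0,
                                           dose_low_threshold_mg=99.0))
    assert base.iloc[0]["label"] == tight.iloc[0]["label"] == "intermittent"
    assert base.iloc[0]["decision_step"] == "instruction"


def test_input_order_does_not_change_labels():
    rx = pd.concat([
        _ocs(["2012-05-01", "2012-01-01"], instruction="as directed"),
        _ocs(["2012-03-01"], instruction="8 tablets daily"),
    ])
    a, _ = cl.classify_patient(rx, NO_EVENTS)
    b, _ = cl.classify_patient(rx.iloc[::-1], NO_EVENTS)
    pd.testing.assert_frame_equal(a.sort_values("date").reset_index(drop=True),
                                  b.sort_values("date").reset_index(drop=True))
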