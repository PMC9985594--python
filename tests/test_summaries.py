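"""Stratifiers, summary tables and the chi-square machinery."""
import numpy as np
import pandas as pd
import pytest

from ocspatterns import summaries as sm


class TestPercent:
    @pytest.mark.parametrize("n,total,expected", [
        (198422, 476167, 41.7),
        (0, 5, 0.0),
        (1, 3, 33.3),
        (1, 8, 12.5),
        (1, 16, 6.3),   # 6.25% rounds half away from zero at the tenths digit
        (1, 2000, 0.1),  # 0.05% likewise
    ])
    def test_values(self, n, total, expected):
        assert sm.percent(n, total) == expected

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            sm.percent(1, 0)

    def test_monotone_in_n(self):
        vals = [sm.percent(n, 997) for n in range(998)]
        assert vals == sorted(vals)


@pytest.mark.parametrize("age,band", [
    (4, "child"), (11, "child"), (12, "adolescent"),
    (17, "adolescent"), (18, "adult"), (80, "adult"),
])
def test_age_bands(age, band):
    assert sm.age_band(age) == band


def test_age_below_minimum_is_an_error():
    with pytest.raises(ValueError):
        sm.age_band(3)


@pytest.mark.parametrize("fills,band", [(0, "0"), (1, "1-2"), (2, "1-2"), (7, ">=3")])
def test_saba_bands(fills, band):
    assert sm.saba_band(fills) == band


def test_saba_window_excludes_index_day():
    index = pd.Timestamp("2012-06-01")
    rx = pd.DataFrame({
        "patient_id": "p",
        "date": [index, index - pd.Timedelta(days=1),
                 index - pd.Timedelta(days=365), index - pd.Timedelta(days=366)],
        "therapy_class": "SABA",
    })
    # index day and anything >365 days before are outside the window
    assert sm.count_saba_fills(rx, index) == "1-2"


class TestGinaStep:
    def _rx(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "date", "drug",
                                           "therapy_class", "strength_mg_per_unit",
                                           "quantity_units", "instruction_text"])

    def _row(self, drug, cls, strength, instr):
        return ("p", pd.Timestamp("2012-01-01"), drug, cls, strength, 1.0, instr)

    def test_no_medication_is_step_zero(self):
        assert sm.assign_gina_step(self._rx([])) == 0

    def test_saba_only_is_step_one(self):
        rx = self._rx([self._row("salbutamol", "SABA", 0.1, "prn")])
        assert sm.assign_gina_step(rx) == 1

    def test_low_dose_ics_is_step_two(self):
        rx = self._rx([self._row("beclometasone", "ICS", 0.1, "two puffs twice daily")])
        assert sm.assign_gina_step(rx) == 2

    def test_low_dose_ics_laba_is_step_three(self):
        rx = self._rx([self._row("fluticasone_propionate", "ICS_LABA", 0.05,
                                 "two puffs twice daily")])
        assert sm.assign_gina_step(rx) == 3

    def test_medium_dose_ics_laba_is_step_four(self):
        rx = self._rx([self._row("beclometasone", "ICS_LABA", 0.2,
                                 "two puffs twice daily")])
        assert sm.assign_gina_step(rx) == 4

    def test_high_dose_ics_laba_is_step_five(self):
        rx = self._rx([self._row("beclometasone", "ICS_LABA", 0.25,
                                 "two puffs twice daily")])
        assert sm.assign_gina_step(rx) == 5

    def test_biologic_is_step_five(self):
        rx = self._rx([self._row("omalizumab", "biologic", 75.0, "")])
        assert sm.assign_gina_step(rx) == 5

    def test_unknown_class_ignored_with_warning(self):
        rx = self._rx([self._row("thing", "vitamin", 1.0, "")])
        with pytest.warns(UserWarning):
            assert sm.assign_gina_step(rx) == 0


class TestSummarizePatterns:
    def test_single_once_only_patient(self):
        profiles = pd.DataFrame({"patient_id": ["a"], "detailed_label": ["Once-only"],
                                 "n_scripts": [1]})
        table = sm.summarize_patterns(profiles)
        row = table.set_index("label").loc["Once-only"]
        assert row["n"] == 1 and row["mean_rx"] == 1.0 and row["median_rx"] == 1.0

    def test_quartiles_by_linear_interpolation(self):
        profiles = pd.DataFrame({
            "patient_id": list("abc"),
            "detailed_label": ["Sporadic"] * 3,
            "n_scripts": [2, 2, 3],
        })
        row = sm.summarize_patterns(profiles).set_index("label").loc["Sporadic"]
        assert row["mean_rx"] == pytest.approx(7 / 3)
        assert row["median_rx"] == 2.0
        assert (row["q1_rx"], row["q3_rx"]) == (2.0, 2.5)

    def test_super_rows_sum_their_members(self, sim_bundle):
        from ocspatterns import classifier, cohort, patterns
        c, _ = cohort.build_cohort(sim_bundle.patients, sim_bundle.prescriptions,
                                   sim_bundle.events)
        scripts, use = classifier.classify_cohort(c, sim_bundle.prescriptions,
                                                  sim_bundle.events)
        profiles = patterns.profiles_frame(scripts, use)
        table = sm.summarize_patterns(profiles).set_index("label")
        counts = profiles["detailed_label"].value_counts().to_dict()
        agg = sm.aggregate_detailed_counts(counts)
        for super_row in ("Any infrequent", "Any moderately frequent", "Any frequent"):
            assert table.loc[super_row, "n"] == agg[super_row]
        assert table.loc["Total", "n"] == len(profiles)


class TestChiSquare:
    def test_pearson_statistic_against_closed_form(self):
        # hand computation: all expected cells are 15, each deviation is 5,
        # so X^2 = 4 * 25/15 = 20/3
        res = sm.chisq_from_table([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert res.dof == 1

    def test_identical_rows_give_zero(self):
        res = sm.chisq_from_table([[5, 10, 15], [5, 10, 15]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_uniform_3x3(self):
        res = sm.chisq_from_table(np.full((3, 3), 7))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.dof == 4

    def test_row_permutation_invariance(self):
        tab = np.array([[12, 7, 1], [3, 14, 9], [8, 2, 2]])
        a = sm.chisq_from_table(tab)
        b = sm.chisq_from_table(tab[::-1])
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            res = sm.chisq_from_table([[10, 20, 0], [20, 10, 0]])
        assert res.table.shape == (2, 2)

    def test_crosstab_from_labels(self):
        labels = pd.Series(["a"] * 30 + ["b"] * 30)
        strata = pd.Series(["x"] * 10 + ["y"] * 20 + ["x"] * 20 + ["y"] * 10)
        res = sm.crosstab_and_chisq(labels, strata)
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)


def test_published_table_loads_with_expected_shape():
    table = sm.load_published_pattern_table()
    assert list(table.columns[:3]) == ["label", "kind", "n"]
    assert (table["kind"] == "leaf").sum() == 16
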