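"""The 8-bin longitudinal encoding: schedules, binary/lab/survey blocks,
utilization and the ten fine-tuning aggregates."""

import numpy as np
import pandas as pd
import pytest

from riskpipe.features import (BIN_EDGES_DAYS, DEFAULT_LAB_SPECS, N_BINS,
                               PULSE_PRESSURE_SPEC, BinSchedule, LabSpec,
                               LeakageError, aggregate_finetune, compute_utilization,
                               encode_binary, encode_cohort, encode_lab,
                               encode_surveys, make_time_bins)
from riskpipe._dates import as_days

from conftest import make_population

T = "2017-01-01"


class TestBinSchedule:
    def test_widths_cover_seven_and_a_half_years(self):
        total = BIN_EDGES_DAYS[-1]
        assert abs(total - 7.5 * 365.25) <= 1.0
        widths = np.diff(BIN_EDGES_DAYS)
        months = widths / (365.25 / 12)
        assert np.allclose(np.round(months), [3, 3, 6, 6, 12, 12, 24, 24], atol=0)

    def test_bin_intervals_end_at_prediction(self):
        sch = make_time_bins(T)
        t = as_days(T)
        assert sch.intervals[0] == (t - 91, t)
        assert sch.intervals[7] == (t - 2739, t - 2009)

    def test_every_day_in_window_belongs_to_exactly_one_bin(self):
        """Brute-force day-by-bin membership scan against bin_of."""
        sch = make_time_bins(T)
        t = sch.time_of_prediction
        days = np.arange(t - BIN_EDGES_DAYS[-1], t)
        fast = sch.bin_of(days)
        for day, b in zip(days[::37], fast[::37]):  # stride keeps it quick
            member = [i for i, (lo, hi) in enumerate(sch.intervals)
                      if lo <= day < hi]
            assert member == [b]
        # full partition property
        assert (fast >= 0).all()
        counts = np.bincount(fast, minlength=N_BINS)
        assert counts.sum() == len(days)

    def test_boundary_event_goes_to_more_recent_bin(self):
        sch = make_time_bins(T)
        t = sch.time_of_prediction
        # day exactly at the bin0/bin1 boundary (t - 91) opens bin 0
        assert sch.bin_of(np.array([t - 91]))[0] == 0
        assert sch.bin_of(np.array([t - 92]))[0] == 1

    def test_event_at_or_after_prediction_is_leakage(self):
        sch = make_time_bins(T)
        with pytest.raises(LeakageError):
            sch.bin_of(np.array([sch.time_of_prediction]))
        with pytest.raises(LeakageError):
            sch.bin_of(np.array([sch.time_of_prediction + 3]))


class TestEncodeBinary:
    def test_presence_coding_is_idempotent(self):
        sch = make_time_bins(T)
        ev = pd.DataFrame({"variable": ["a", "a"],
                           "date": ["2016-12-01", "2016-12-20"]})
        blk = encode_binary(ev, sch, ["a", "b"])
        assert blk[0, 0] == 1 and blk.sum() == 1

    def test_no_events_all_zero(self):
        sch = make_time_bins(T)
        blk = encode_binary(pd.DataFrame(columns=["variable", "date"]), sch, ["a"])
        assert blk.sum() == 0

    def test_events_older_than_window_ignored(self):
        sch = make_time_bins(T)
        ev = pd.DataFrame({"variable": ["a"], "date": ["2001-01-01"]})
        assert encode_binary(ev, sch, ["a"]).sum() == 0


class TestEncodeLab:
    def test_pulse_pressure_reference_range_is_all_zero(self):
        sch = make_time_bins(T)
        m = pd.DataFrame({"date": ["2016-11-01"], "value": [40.0]})
        blk = encode_lab(m, sch, PULSE_PRESSURE_SPEC)
        assert blk.sum() == 0  # 30-50 mm Hg is the dropped reference

    @pytest.mark.parametrize("value,level", [(25.0, "low"), (60.0, "high"),
                                             (80.0, "very_high")])
    def test_pulse_pressure_levels(self, value, level):
        sch = make_time_bins(T)
        m = pd.DataFrame({"date": ["2016-11-01"], "value": [value]})
        blk = encode_lab(m, sch, PULSE_PRESSURE_SPEC)
        coded = PULSE_PRESSURE_SPEC.coded_levels
        assert blk[coded.index(level), 0] == 1

    def test_imputation_carries_forward_then_backward(self):
        """A single measurement in bin 5 fills every bin; no NA anywhere."""
        sch = make_time_bins(T)
        # bin 5 covers (913, 1278] days back
        date = np.datetime64(as_days(T) - 1000, "D")
        m = pd.DataFrame({"date": [date], "value": [80.0]})
        blk = encode_lab(m, sch, PULSE_PRESSURE_SPEC)
        coded = PULSE_PRESSURE_SPEC.coded_levels
        assert (blk[coded.index("very_high")] == 1).all()
        assert blk[coded.index("NA")].sum() == 0

    def test_na_only_when_no_measurement_in_whole_window(self):
        sch = make_time_bins(T)
        blk = encode_lab(pd.DataFrame(columns=["date", "value"]), sch,
                         PULSE_PRESSURE_SPEC)
        coded = PULSE_PRESSURE_SPEC.coded_levels
        assert (blk[coded.index("NA")] == 1).all()
        assert blk.sum() == N_BINS

    def test_malformed_spec_rejected(self):
        with pytest.raises(ValueError):
            LabSpec("x", (1.0,), ("a", "b", "c"))
        with pytest.raises(ValueError):
            LabSpec("x", (1.0,), ("a", "b"), reference="zzz")


class TestEncodeSurveys:
    def test_never_surveyed_gets_na_category(self):
        sch = make_time_bins(T)
        out = encode_surveys(pd.DataFrame(columns=["lab", "date", "value"]), sch)
        for name, blk in out.items():
            assert blk.sum() == N_BINS  # NA active in all bins

    def test_lowest_band_is_reference(self):
        sch = make_time_bins(T)
        rec = pd.DataFrame({"lab": ["phq9_total"], "date": ["2016-10-01"],
                            "value": [2.0]})
        out = encode_surveys(rec, sch)
        assert out["phq9_total"].sum() == 0

    def test_item9_is_its_own_variable(self):
        sch = make_time_bins(T)
        rec = pd.DataFrame({"lab": ["phq9_total", "phq9_item9"] ,
                            "date": ["2016-10-01"] * 2, "value": [21.0, 3.0]})
        out = encode_surveys(rec, sch)
        assert out["phq9_total"][:, 0].sum() == 1
        assert out["phq9_item9"][:, 0].sum() == 1

    def test_score_outside_instrument_range_rejected(self):
        sch = make_time_bins(T)
        rec = pd.DataFrame({"lab": ["phq9_total"], "date": ["2016-10-01"],
                            "value": [31.0]})
        with pytest.raises(ValueError):
            encode_surveys(rec, sch)


class TestUtilization:
    def test_full_grid_gives_600(self):
        assert compute_utilization(np.ones((1, 75 * 8)))[0] == 600

    def test_empty_row_gives_zero(self):
        assert compute_utilization(np.zeros((1, 75 * 8)))[0] == 0

    def test_one_variable_three_bins(self):
        row = np.zeros(75 * 8)
        row[[0, 3, 7]] = 1
        assert compute_utilization(row)[0] == 3


class TestEncodeCohort:
    def _pop(self):
        return make_population(
            patients=[{"patient_id": 1, "dob": "1960-06-01", "sex": "F",
                       "race": "black", "ethnicity": "hispanic",
                       "area_deprivation": 0.5},
                      {"patient_id": 2, "dob": "1940-06-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": -0.2}],
            events=[{"patient_id": 1, "date": "2016-12-01",
                     "variable": "suicide_ideation", "code": "R45.851",
                     "code_system": "ICD10"},
                    {"patient_id": 1, "date": "2010-06-01",
                     "variable": "chronic_pain", "code": "G89.4",
                     "code_system": "ICD10"},
                    # event after prediction date: outside this row's window
                    {"patient_id": 2, "date": "2018-01-01",
                     "variable": "chronic_pain", "code": "G89.4",
                     "code_system": "ICD10"}],
            labs=[{"patient_id": 1, "date": "2016-11-15", "lab": "systolic",
                   "value": 160.0},
                  {"patient_id": 1, "date": "2016-11-15", "lab": "diastolic",
                   "value": 70.0}])

    def test_longitudinal_block_is_nvars_times_eight(self):
        pop = self._pop()
        cohort = pd.DataFrame({"patient_id": [1, 2],
                               "time_of_prediction": [T, T]})
        fm = encode_cohort(cohort, pop)
        nb = (fm.meta["block"] == "binary").sum()
        assert nb == len(pop.variable_list) * N_BINS

    def test_binary_cells_and_windowing(self):
        pop = self._pop()
        cohort = pd.DataFrame({"patient_id": [1, 2],
                               "time_of_prediction": [T, T]})
        fm = encode_cohort(cohort, pop)
        df = fm.to_frame()
        assert df.loc[0, "suicide_ideation__bin0"] == 1
        # 2010-06-01 is ~6.6 years before 2017-01-01 -> bin 7
        assert df.loc[0, "chronic_pain__bin7"] == 1
        assert df.loc[1, [c for c in df.columns if "chronic_pain" in c]].sum() == 0

    def test_pulse_pressure_derived_from_bp_pair(self):
        pop = self._pop()
        cohort = pd.DataFrame({"patient_id": [1], "time_of_prediction": [T]})
        fm = encode_cohort(cohort, pop)
        df = fm.to_frame()
        assert df.loc[0, "pulse_pressure__very_high__bin0"] == 1  # 160-70=90

    def test_row_independence_under_permutation(self):
        pop = self._pop()
        cohort = pd.DataFrame({"patient_id": [1, 2],
                               "time_of_prediction": [T, T]})
        fm = encode_cohort(cohort, pop)
        fm_r = encode_cohort(cohort.iloc[::-1].reset_index(drop=True), pop)
        assert np.array_equal(fm.X[::-1], fm_r.X)

    def test_demographics_enter_once_with_reference_coding(self):
        pop = self._pop()
        cohort = pd.DataFrame({"patient_id": [1, 2],
                               "time_of_prediction": [T, T]})
        fm = encode_cohort(cohort, pop)
        demo = fm.meta.loc[fm.meta["block"] == "demographic"]
        assert (demo["bin"] == -1).all()
        df = fm.to_frame()
        assert df.loc[0, "sex__F"] == 1 and df.loc[1, "sex__F"] == 0
        assert "sex__M" not in df.columns  # reference dropped


class TestFineTuneAggregates:
    def test_vector_has_ten_entries_and_any_bin_rule(self):
        pop = make_population(
            patients=[{"patient_id": 1, "dob": "1950-01-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": 0.0}],
            events=[{"patient_id": 1, "date": "2010-06-01",  # bin 7 only
                     "variable": "suicide_ideation", "code": "R45.851",
                     "code_system": "ICD10"}])
        cohort = pd.DataFrame({"patient_id": [1], "time_of_prediction": [T]})
        fm = encode_cohort(cohort, pop)
        ft = aggregate_finetune(fm, pop)
        assert ft.shape[1] == 10
        assert ft.loc[0, "suicide_ideation"] == 1.0
        assert 0 <= ft.loc[0, "usage"] <= 600

    def test_reference_patient_is_all_zero(self):
        pop = make_population(
            patients=[{"patient_id": 1, "dob": "1957-01-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": 0.0}])
        cohort = pd.DataFrame({"patient_id": [1], "time_of_prediction": [T]})
        fm = encode_cohort(cohort, pop)
        ft = aggregate_finetune(fm, pop)  # age 60: neither young nor old
        assert ft.iloc[0].sum() == 0.0
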