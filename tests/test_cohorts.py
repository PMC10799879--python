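"""Study-design construction: DOB partitioning, Rcc matching, calendar and
event-triggered cohorts."""

import numpy as np
import pandas as pd
import pytest

from riskpipe.cohorts import (CohortShortfallError, RccConfig,
                              assign_dob_partitions, build_calendar_cohort,
                              build_event_cohort, build_rcc, compute_outcomes)
from riskpipe.outcomes import classify_events

from conftest import make_population


class TestDobPartitions:
    def test_exact_division(self):
        pats = pd.DataFrame({"patient_id": range(1000),
                             "dob": pd.date_range("1930-01-01", periods=1000)})
        parts = assign_dob_partitions(pats, k=100)
        assert (parts.groupby("dob_partition").size() == 10).all()

    def test_ordering_oldest_first(self):
        pats = pd.DataFrame({"patient_id": [5, 1, 9],
                             "dob": pd.to_datetime(["1980-01-01", "1930-01-01",
                                                    "1955-06-01"])})
        parts = assign_dob_partitions(pats, k=3).set_index("patient_id")
        assert parts.loc[1, "dob_partition"] == 0
        assert parts.loc[5, "dob_partition"] == 2

    def test_even_odd_masks_partition_everyone(self, small_pop, small_parts):
        even = small_parts["even"].to_numpy()
        assert even.sum() + (~even).sum() == len(small_pop.patients)
        assert set(small_parts.loc[small_parts.even, "dob_partition"] % 2) == {0}

    def test_too_few_patients_rejected(self):
        pats = pd.DataFrame({"patient_id": [1], "dob": ["1950-01-01"]})
        with pytest.raises(ValueError):
            assign_dob_partitions(pats, k=5)


@pytest.fixture(scope="module")
def rcc(small_pop_m, small_parts_m, small_outcomes_m):
    return build_rcc(small_pop_m, small_outcomes_m, RccConfig(seed=7),
                     partitions=small_parts_m,
                     calendar_range=("2000-01-01", "2022-01-01"))


# module-scoped clones of the session fixtures (pytest fixture scoping)
@pytest.fixture(scope="module")
def small_pop_m(small_pop):
    return small_pop


@pytest.fixture(scope="module")
def small_parts_m(small_pop):
    from riskpipe.cohorts import assign_dob_partitions
    return assign_dob_partitions(small_pop.patients, k=10)


@pytest.fixture(scope="module")
def small_outcomes_m(small_outcomes):
    return small_outcomes


class TestRcc:
    def test_four_controls_per_case(self, rcc):
        n_cases = int(rcc["is_case"].sum())
        assert (~rcc["is_case"]).sum() == 4 * n_cases

    def test_gap_is_exactly_45_days(self, rcc):
        gap = (pd.to_datetime(rcc["event_date"])
               - pd.to_datetime(rcc["time_of_prediction"])).dt.days
        assert (gap == 45).all()

    def test_partition_distribution_matches_exactly(self, rcc):
        cases = rcc.loc[rcc["is_case"]].groupby("dob_partition").size()
        ctrls = rcc.loc[~rcc["is_case"]].groupby("dob_partition").size()
        assert (ctrls == 4 * cases).all()

    def test_control_dates_within_case_span(self, rcc):
        for part, grp in rcc.groupby("dob_partition"):
            case_days = pd.to_datetime(grp.loc[grp.is_case, "event_date"])
            ctrl_days = pd.to_datetime(grp.loc[~grp.is_case, "event_date"])
            assert ctrl_days.min() >= case_days.min()
            assert ctrl_days.max() <= case_days.max()

    def test_controls_have_no_outcome(self, rcc, small_outcomes_m):
        with_outcome = set(small_outcomes_m["patient_id"])
        ctrl = rcc.loc[~rcc["is_case"], "patient_id"]
        assert not ctrl.isin(with_outcome).any()

    def test_reproducible_under_fixed_seed(self, small_pop_m, small_parts_m,
                                           small_outcomes_m, rcc):
        again = build_rcc(small_pop_m, small_outcomes_m, RccConfig(seed=7),
                          partitions=small_parts_m,
                          calendar_range=("2000-01-01", "2022-01-01"))
        pd.testing.assert_frame_equal(rcc, again)

    def test_visit_weighted_controls_over_represent_heavy_users(
            self, rcc, small_pop_m, small_outcomes_m):
        visits_per = small_pop_m.visits.groupby("patient_id").size()
        ctrl_ids = rcc.loc[~rcc["is_case"], "patient_id"]
        with_outcome = set(small_outcomes_m["patient_id"])
        pool = small_pop_m.patients.loc[
            ~small_pop_m.patients["patient_id"].isin(with_outcome), "patient_id"]
        ctrl_mean = visits_per.reindex(ctrl_ids).fillna(0).mean()
        pool_mean = visits_per.reindex(pool).fillna(0).mean()
        assert ctrl_mean > pool_mean

    def test_shortfall_is_reported_not_silently_reused(self):
        # one case and a single eligible control owner: cannot find 4 distinct
        pop = make_population(
            patients=[{"patient_id": i, "dob": f"19{50+i}-01-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": 0} for i in range(3)],
            visits=[{"patient_id": 1, "date": "2012-06-01", "visit_type": "office"},
                    {"patient_id": 1, "date": "2012-07-01", "visit_type": "office"}],
            events=[{"patient_id": 0, "date": "2012-06-15",
                     "variable": "suicide_attempt", "code": "E9509",
                     "code_system": "ICD9"}])
        oc = pd.DataFrame({"patient_id": [0], "component": ["attempt"],
                           "event_date": [np.datetime64("2012-06-15")],
                           "rule_applied": ["first-attempt"]})
        parts = pd.DataFrame({"patient_id": [0, 1, 2], "dob_partition": [0, 0, 0],
                              "even": [True, True, True]})
        with pytest.raises(CohortShortfallError) as err:
            build_rcc(pop, oc, RccConfig(seed=0), partitions=parts,
                      calendar_range=("2000-01-01", "2022-01-01"))
        assert err.value.report["found"].iloc[0] < 4


class TestCalendarCohort:
    def _pop(self):
        return make_population(
            patients=[{"patient_id": i, "dob": "1960-01-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": 0} for i in range(30)],
            visits=(
                [{"patient_id": 0, "date": "2016-09-01", "visit_type": "office"}]
                + [{"patient_id": 1, "date": "2016-11-15", "visit_type": "office"}]
                + [{"patient_id": 2, "date": "2016-12-01", "visit_type": "office"}]
                + [{"patient_id": i, "date": "2016-11-01", "visit_type": "office"}
                   for i in range(3, 30)]),
            events=(
                # patient 1: attempt 3 days after prediction, nothing later
                [{"patient_id": 1, "date": "2017-01-04",
                  "variable": "suicide_attempt", "code": "T39.1X2A",
                  "code_system": "ICD10"}]),
            deaths=[{"patient_id": 2, "date": "2017-04-11",
                     "cause_codes": "T14.91|ICD10"}])

    def test_lookback_inclusion_and_exclusion_week(self):
        pop = self._pop()
        comp = classify_events(pop.events, pop.deaths)
        coh = build_calendar_cohort(pop, comp, "2017-01-01")
        coh = coh.set_index("patient_id")
        assert 0 not in coh.index          # last visit 4 months before cutoff
        assert not coh.loc[1, "is_case"]   # event inside the 7-day exclusion
        assert coh.loc[2, "is_case"]       # suicide 100 days into follow-up
        assert coh.loc[2, "component"] == "suicide"

    def test_suicide_target_flag_restricts_cases(self):
        pop = self._pop()
        comp = classify_events(pop.events, pop.deaths)
        coh = build_calendar_cohort(pop, comp, "2017-01-01", target="suicide")
        assert set(coh.loc[coh.is_case, "patient_id"]) == {2}

    def test_four_month_lookback_config(self):
        pop = self._pop()
        comp = classify_events(pop.events, pop.deaths)
        coh = build_calendar_cohort(pop, comp, "2017-01-01", lookback_months=4)
        assert 0 in set(coh["patient_id"])


class TestEventCohort:
    def _pop(self):
        return make_population(
            patients=[{"patient_id": i, "dob": "1955-01-01", "sex": "M",
                       "race": "white", "ethnicity": "non_hispanic",
                       "area_deprivation": 0} for i in range(4)],
            visits=(
                # 0: qualifying psych visit inside the initiation window
                [{"patient_id": 0, "date": "2008-03-01", "visit_type": "psych"},
                 # 1: psych visit only after the window closes
                 {"patient_id": 1, "date": "2012-01-01", "visit_type": "psych"},
                 # 2: qualifying, then drops out of care
                 {"patient_id": 2, "date": "2008-06-01", "visit_type": "psych"},
                 # 3: qualifying, dies (non-suicide) four years later
                 {"patient_id": 3, "date": "2008-01-10", "visit_type": "psych"}]),
            events=[{"patient_id": 2, "date": "2014-06-01",  # 6 y after trigger
                     "variable": "suicide_attempt", "code": "E9509",
                     "code_system": "ICD9"}],
            deaths=[{"patient_id": 3, "date": "2012-01-10",
                     "cause_codes": "I21.9|ICD10"}])

    def _build(self):
        pop = self._pop()
        comp = classify_events(pop.events, pop.deaths)
        parts = pd.DataFrame({"patient_id": range(4), "dob_partition": [0, 1, 0, 1],
                              "even": [True, False, True, False]})
        return build_event_cohort(pop, comp, "psychiatric-visit",
                                  initiation_start="2007-07-01",
                                  partitions=parts,
                                  calendar_range=("2000-01-01", "2022-01-01"))

    def test_late_trigger_excluded_and_counted(self):
        coh = self._build()
        assert 1 not in set(coh["patient_id"])
        assert coh.attrs["n_excluded"] == 1

    def test_nonsuicide_death_censors(self):
        coh = self._build().set_index("patient_id")
        assert coh.loc[3, "censored"]
        assert coh.loc[3, "time_to_event_days"] == (
            pd.Timestamp("2012-01-10") - pd.Timestamp("2008-01-10")).days

    def test_dropout_of_care_does_not_censor(self):
        """Event six years after the last visit still counts as an event."""
        coh = self._build().set_index("patient_id")
        assert not coh.loc[2, "censored"]
        assert coh.loc[2, "component"] == "attempt"

    def test_unknown_trigger_rejected(self):
        with pytest.raises(ValueError):
            build_event_cohort(self._pop(), None, "dental-visit")


def test_gap_integrity_no_visible_event_after_prediction(rcc, small_pop_m):
    """Leakage scan across the Rcc design: every encoded cell is pre-gap."""
    from riskpipe.features import encode_cohort
    from riskpipe.metrics import leakage_audit
    sub = rcc.iloc[:120]
    fm = encode_cohort(sub, small_pop_m)
    assert leakage_audit(fm, small_pop_m) == 0
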