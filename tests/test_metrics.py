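"""Discrimination, calibration, concentration of risk and drift metrics,
checked against exhaustive pairwise oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from riskpipe.metrics import (UndefinedMetricError, auprc, auprc_bruteforce,
                              auroc, auroc_pairwise, calibration,
                              calibration_coverage, concentration_of_risk,
                              drift_eval, harrell_c, harrell_c_pairwise)


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 2, 1], [1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2], [1, 1])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        s = rng.integers(0, 10, 500).astype(float)  # many ties
        y = rng.integers(0, 2, 500)
        assert abs(auroc(s, y) - roc_auc_score(y, s)) < 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 300)
        y = rng.integers(0, 2, 300)
        assert abs(auroc(s, y) - auroc(np.exp(2 * s), y)) < 1e-12


class TestAuprc:
    def test_agrees_with_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.integers(0, 8, 200).astype(float)
            y = rng.integers(0, 2, 200)
            assert abs(auprc(s, y) - average_precision_score(y, s)) < 1e-12


class TestHarrellC:
    def test_reduces_to_auroc_without_censoring(self):
        """Cases share one event time, controls censored later: admissible
        pairs are exactly the case-control pairs."""
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200).astype(bool)
        s = rng.normal(0, 1, 200)
        t = np.where(y, 1.0, 2.0)
        assert abs(harrell_c(s, t, y) - auroc(s, y)) < 1e-12

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        s = rng.normal(0, 1, 150)
        t = rng.exponential(10, 150)
        e = rng.integers(0, 2, 150).astype(bool)
        e[0] = True
        c = harrell_c(s, t, e)
        assert abs(harrell_c(-s, t, e) - (1 - c)) < 1e-12

    def test_no_events_undefined(self):
        with pytest.raises(UndefinedMetricError):
            harrell_c([1, 2], [3, 4], [False, False])

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 300)
        t = rng.exponential(10, 300) + rng.random(300) * 1e-6  # no time ties
        e = rng.integers(0, 2, 300).astype(bool)
        e[:3] = True
        # lifelines orders by predicted survival (higher = longer): flip sign
        assert abs(harrell_c(s, t, e) - concordance_index(t, -s, e)) < 1e-9


@pytest.mark.parametrize("seed", range(10))
def test_rank_metrics_match_exhaustive_oracles(seed):
    """Fast implementations equal brute-force pairwise/threshold scans."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 300))
    s = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
    y = rng.integers(0, 2, n)
    if y.sum() in (0, n):
        y[0], y[1] = 0, 1
    assert abs(auroc(s, y) - auroc_pairwise(s, y)) < 1e-12
    assert abs(auprc(s, y) - auprc_bruteforce(s, y)) < 1e-12
    t = np.round(rng.exponential(10, n), 1)
    e = rng.integers(0, 2, n).astype(bool)
    if not e.any():
        e[0] = True
    assert abs(harrell_c(s, t, e) - harrell_c_pairwise(s, t, e)) < 1e-12


class TestCalibration:
    def test_well_specified_model_is_covered(self):
        rng = np.random.default_rng(6)
        s = rng.normal(-2, 1.2, 30_000)
        y = rng.random(30_000) < _sigmoid(s)
        tab = calibration(s, y)
        assert calibration_coverage(tab) >= 0.9

    def test_shift_miscalibration_detected(self):
        rng = np.random.default_rng(7)
        s = rng.normal(-1, 1.0, 30_000)
        y = rng.random(30_000) < _sigmoid(s)
        tab = calibration(s + 1.0, y)  # systematic over-prediction
        big = tab[tab["n"] > 500]
        assert (big["observed"] < big["expected"]).mean() > 0.9

    def test_event_conservation_per_subgroup(self):
        rng = np.random.default_rng(8)
        s = rng.normal(0, 1, 5000)
        y = rng.integers(0, 2, 5000)
        g = rng.choice(["a", "b"], 5000)
        tab = calibration(s, y, subgroups=g)
        for grp in ("a", "b"):
            sub = tab[tab["subgroup"] == grp]
            assert sub["n"].sum() == (g == grp).sum()
            assert sub["n_events"].sum() == y[g == grp].sum()

    def test_zero_event_bins_no_division_errors(self):
        s = np.linspace(-3, 3, 200)
        y = np.zeros(200)
        y[-1] = 1  # single event far right
        tab = calibration(s, y)
        assert (tab["observed"] >= 0).all()

    def test_small_subgroups_skipped(self):
        s = np.r_[np.zeros(100), 1.0]
        y = np.r_[np.zeros(100), 1.0]
        g = np.r_[["big"] * 100, ["tiny"]]
        tab = calibration(s, y, subgroups=g)
        assert set(tab["subgroup"]) == {"big"}


class TestConcentrationOfRisk:
    def test_null_scores_give_ratio_near_one(self):
        rng = np.random.default_rng(9)
        s = rng.normal(0, 1, 100_000)
        y = rng.random(100_000) < 0.02
        tab = concentration_of_risk(s, y, 0.01)
        assert abs(tab["concentration"].iloc[0] - 1.0) < 0.35

    def test_perfect_ranking_closed_form(self):
        """With q <= prevalence, perfect ranking gives exactly 1/prevalence."""
        n, p = 100_000, 0.02
        y = np.zeros(n, dtype=bool)
        y[: int(n * p)] = True
        s = np.where(y, 1.0, 0.0) + np.linspace(0, 0.1, n)[::-1]
        tab = concentration_of_risk(s, y, 0.01)
        assert tab["concentration"].iloc[0] == pytest.approx(1 / p, abs=1e-12)

    def test_ratio_bounded_by_inverse_prevalence(self):
        rng = np.random.default_rng(10)
        s = rng.normal(0, 1, 20_000)
        y = rng.random(20_000) < 0.05
        tab = concentration_of_risk(s + 2 * y, y, [0.01, 0.001])
        assert (tab["concentration"] <= 1 / y.mean() + 1e-9).all()

    def test_nested_strata(self):
        rng = np.random.default_rng(11)
        s = rng.normal(0, 1, 10_000)
        y = rng.random(10_000) < 0.05
        tab = concentration_of_risk(s, y, [0.01, 0.001])
        order = np.lexsort((np.arange(len(s)), -s))
        top1 = set(order[:100])
        top01 = set(order[:10])
        assert top01 <= top1

    def test_too_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            concentration_of_risk([1, 2, 3], [0, 1, 0], 0.001)

    def test_component_breakdown(self):
        rng = np.random.default_rng(12)
        n = 10_000
        comp = rng.choice(["none", "attempt", "suicide"], n, p=[0.95, 0.04, 0.01])
        y = comp != "none"
        s = rng.normal(0, 1, n) + (comp == "suicide") * 2
        tab = concentration_of_risk(s, y, 0.01, components=comp)
        sui = tab[(tab["component"] == "suicide")]
        att = tab[(tab["component"] == "attempt")]
        assert sui["concentration"].iloc[0] > att["concentration"].iloc[0]


class TestDrift:
    def test_null_drift_frozen_equals_refreshed(self):
        rng = np.random.default_rng(13)
        s = rng.normal(0, 1, 5000)
        y = rng.random(5000) < _sigmoid(s - 3)
        if y.sum() < 5:
            y[:5] = True
        rep = drift_eval(s, s, y)
        assert rep.loc[0, "auroc"] == rep.loc[1, "auroc"]

    def test_injected_shift_visible_in_mean_score(self):
        rng = np.random.default_rng(14)
        s = rng.normal(0, 1, 5000)
        y = rng.random(5000) < _sigmoid(s - 3)
        if y.sum() < 5:
            y[:5] = True
        rep = drift_eval(s + 1.0, s, y).set_index("model")
        assert rep.loc["frozen", "mean_score"] > rep.loc["refreshed", "mean_score"]
        # rank metric unchanged by the shift
        assert abs(rep.loc["frozen", "auroc"] - rep.loc["refreshed", "auroc"]) < 1e-12
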