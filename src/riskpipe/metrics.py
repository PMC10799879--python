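"""Model evaluation: discrimination, subgroup calibration, concentration of
risk, leakage auditing and drift comparison.

The rank metrics are implemented directly from their probabilistic
definitions — AUROC as the probability that a random case outscores a random
control (ties count one half), Harrell's c as its right-censored analogue
over admissible pairs — with exhaustive pairwise oracles available for
verification. Calibration tables stratify log-odds scores into fixed-width
bins and compare observed event fractions to the probability the logistic
score implies. Concentration of risk is the event rate inside a top score
stratum divided by the overall event rate, the screening-oriented summary
used to size outreach programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    pass


def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# discrimination

def auroc(scores, labels) -> float:
    """P(random case outscores a random control), ties counting one half.

    Computed from midranks (the Mann-Whitney U formulation), so ties are
    exact, not trapezoid-approximated.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("need at least one case and one control")
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auroc_pairwise(scores, labels) -> float:
    """Exhaustive O(n_case * n_control) oracle for :func:`auroc`."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    cases, controls = s[y], s[~y]
    if len(cases) == 0 or len(controls) == 0:
        raise UndefinedMetricError("need at least one case and one control")
    diff = cases[:, None] - controls[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average precision).

    Step-sum AP over distinct score thresholds in decreasing order:
    ``sum (R_k - R_{k-1}) * P_k``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    n_pos = y.sum()
    if n_pos == 0 or n_pos == len(y):
        raise UndefinedMetricError("need at least one case and one control")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at the last index of each distinct threshold
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def auprc_bruteforce(scores, labels) -> float:
    """Per-threshold counting oracle for :func:`auprc`."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise UndefinedMetricError("need at least one case and one control")
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(s), reverse=True):
        sel = s >= thr
        tp = int((y & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def harrell_c(scores, times, events) -> float:
    """Concordance index over admissible pairs under right censoring.

    A pair (i, j) is admissible when i has an event and either ``t_i < t_j``
    or ``t_i == t_j`` with j censored; concordance means the event-bearing
    patient has the higher score, score ties counting one half. Computed in
    vectorized row blocks so cohort-sized inputs stay fast.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if (t < 0).any():
        raise UndefinedMetricError("times must be nonnegative")
    if not e.any():
        raise UndefinedMetricError("no events: concordance undefined")
    num = den = 0.0
    idx = np.flatnonzero(e)
    for blk in np.array_split(idx, max(1, len(idx) // 512)):
        ti = t[blk][:, None]
        si = s[blk][:, None]
        adm = (ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :])
        den += adm.sum()
        num += ((si > s[None, :]) & adm).sum() + 0.5 * ((si == s[None, :]) & adm).sum()
    if den == 0:
        raise UndefinedMetricError("no admissible pairs")
    return float(num / den)


def harrell_c_pairwise(scores, times, events) -> float:
    """Explicit double-loop oracle with the same admissibility rule."""
    s = list(map(float, scores))
    t = list(map(float, times))
    e = list(map(bool, events))
    num = den = 0.0
    n = len(s)
    for i in range(n):
        if not e[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            if t[i] < t[j] or (t[i] == t[j] and not e[j]):
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    if den == 0:
        raise UndefinedMetricError("no admissible pairs")
    return num / den


# ---------------------------------------------------------------------------
# calibration

def calibration(scores, labels, subgroups=None, bin_width: float = 0.5,
                min_subgroup: int = 11) -> pd.DataFrame:
    """Calibration table by subgroup and score bin.

    ``scores`` are log-odds. Bins are fixed-width intervals aligned to
    multiples of ``bin_width``; per (subgroup, bin) the table reports n,
    event count, observed fraction with an exact (Clopper-Pearson) 95%
    interval, ``expected`` = sigmoid of the bin center, and
    ``expected_mean`` = the mean predicted probability of the scores in the
    bin (the exact well-specified reference). Subgroups smaller than
    ``min_subgroup`` are skipped with a log entry.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if subgroups is None:
        subgroups = np.full(len(s), "all")
    g = np.asarray(subgroups)
    rows = []
    for grp in pd.unique(g):
        sel = g == grp
        if sel.sum() < min_subgroup:
            log.info("skipping subgroup %r with %d < %d rows", grp, sel.sum(),
                     min_subgroup)
            continue
        ss, yy = s[sel], y[sel]
        b = np.floor(ss / bin_width).astype(int)
        for bi in np.unique(b):
            m = b == bi
            n = int(m.sum())
            k = int(yy[m].sum())
            center = (bi + 0.5) * bin_width
            lo, hi = _clopper_pearson(k, n)
            rows.append({"subgroup": grp, "bin_center": center, "n": n,
                         "n_events": k, "observed": k / n,
                         "ci_low": lo, "ci_high": hi,
                         "expected": float(_sigmoid(center)),
                         "expected_mean": float(_sigmoid(ss[m]).mean())})
    return pd.DataFrame(rows)


def _clopper_pearson(k, n, alpha=0.05):
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def calibration_coverage(table: pd.DataFrame, level: float = 0.95) -> float:
    """Fraction of bins whose event count lies inside the central binomial
    interval implied by the bin's mean predicted probability."""
    ok = 0
    for _, r in table.iterrows():
        lo, hi = stats.binom.interval(level, int(r["n"]), r["expected_mean"])
        ok += lo <= r["n_events"] <= hi
    return ok / len(table)


# ---------------------------------------------------------------------------
# concentration of risk

def concentration_of_risk(scores, labels, q, components=None) -> pd.DataFrame:
    """Event concentration in the top-``q`` score stratum.

    ``q`` may be a float or a list (e.g. ``[0.01, 0.001]``). ``labels`` is
    binary overall; ``components`` optionally maps each row to a component
    name ("suicide"/"attempt"/"overdose"/"none") for a per-component
    breakdown. Rows are ranked by score with deterministic tie-breaks, so
    strata are nested. The ratio is (event fraction in stratum) / (overall
    event fraction); under label-independent scores it is ~1, under perfect
    ranking with q <= prevalence it is exactly 1/prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if ((qs <= 0) | (qs >= 1)).any():
        raise ValueError("q must be in (0, 1)")
    order = np.lexsort((np.arange(len(s)), -s))  # stable rank by descending score
    comp = np.asarray(components) if components is not None else None
    overall = y.mean()
    rows = []
    for qq in qs:
        k = int(round(qq * len(s)))
        if k < 1:
            raise ValueError(f"stratum for q={qq} would hold < 1 row")
        top = order[:k]
        frac = y[top].mean()
        rows.append({"q": qq, "component": "all", "n_stratum": k,
                     "n_events": int(y[top].sum()), "stratum_fraction": float(frac),
                     "overall_fraction": float(overall),
                     "concentration": float(frac / overall) if overall > 0 else np.nan})
        if comp is not None:
            for c in [c for c in pd.unique(comp) if c != "none"]:
                yc = comp == c
                oc = yc.mean()
                rows.append({"q": qq, "component": c, "n_stratum": k,
                             "n_events": int(yc[top].sum()),
                             "stratum_fraction": float(yc[top].mean()),
                             "overall_fraction": float(oc),
                             "concentration": float(yc[top].mean() / oc) if oc > 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leakage audit

def leakage_audit(fm, population) -> int:
    """Brute-force scan: re-derive the binary block row by row from raw event
    dates and count feature cells that could only come from an event at or
    after the row's time of prediction. Returns the violation count (0 when
    the encoding is leakage-safe) and raises on any reconstruction mismatch.
    """
    from riskpipe.features import BIN_EDGES_DAYS, N_BINS, _as_day_array
    meta = fm.meta
    bin_cols = np.flatnonzero((meta["block"] == "binary").to_numpy())
    variables = meta["variable"].to_numpy()
    bins = meta["bin"].to_numpy()
    ev = population.events
    ev_day = _as_day_array(ev["date"])
    ev_by_pid = {pid: (grp_days, grp_vars) for pid, grp_days, grp_vars in
                 ((p, ev_day[ix.to_numpy()], ev["variable"].to_numpy()[ix.to_numpy()])
                  for p, ix in ev.groupby("patient_id").groups.items())}
    t_rows = _as_day_array(fm.cohort["time_of_prediction"])
    violations = 0
    for r, (pid, t) in enumerate(zip(fm.cohort["patient_id"].to_numpy(), t_rows)):
        days, vars_ = ev_by_pid.get(pid, (np.empty(0, dtype=np.int64),
                                          np.empty(0, dtype=object)))
        for ci in bin_cols:
            v, b = variables[ci], bins[ci]
            in_bin = (vars_ == v) & (days >= t - BIN_EDGES_DAYS[b + 1]) \
                & (days < t - BIN_EDGES_DAYS[b])
            expect = 1.0 if in_bin.any() else 0.0
            got = fm.X[r, ci]
            if got != expect:
                raise AssertionError(
                    f"row {r} ({pid}) column {meta['column'].iloc[ci]}: "
                    f"encoded {got}, brute force {expect}")
            if got == 1.0:
                legit = in_bin & (days < t)
                if not legit.any():
                    violations += 1
    return violations


def out_of_half_audit(even_mask, score_source) -> int:
    """Count rows whose evaluation score came from a model trained on their
    own even/odd half (must be 0 under the even/odd protocol)."""
    even_mask = np.asarray(even_mask, dtype=bool)
    src = np.asarray(score_source)
    bad = ((even_mask) & (src == "even-trained")) | ((~even_mask) & (src == "odd-trained"))
    return int(bad.sum())


# ---------------------------------------------------------------------------
# drift

def drift_eval(frozen_scores, refreshed_scores, labels,
               qs=(0.01, 0.001)) -> pd.DataFrame:
    """Paired frozen-vs-refreshed report on one later-calendar cohort.

    ``frozen_scores`` come from a fine-tuning frozen at the earlier
    prediction date; ``refreshed_scores`` from fine-tuning refit on the
    later cohort (out-of-half). Reports AUROC and top-strata event counts
    for each.
    """
    y = np.asarray(labels).astype(bool)
    rows = []
    for name, sc in (("frozen", frozen_scores), ("refreshed", refreshed_scores)):
        sc = np.asarray(sc, dtype=float)
        rec = {"model": name, "auroc": auroc(sc, y),
               "mean_score": float(sc.mean())}
        cor = concentration_of_risk(sc, y, list(qs))
        for _, r in cor.iterrows():
            rec[f"top{r['q']:g}_events"] = r["n_events"]
            rec[f"top{r['q']:g}_cor"] = r["concentration"]
        rows.append(rec)
    return pd.DataFrame(rows)
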