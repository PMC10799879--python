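"""Study-design construction: Rcc, calendar prospective, event-triggered
time-to-event cohorts, and date-of-birth partitioning.

Four designs share one observation-window convention (features strictly
before the time of prediction):

- **Rcc** — retrospective nested case-control. Each case's time of
  prediction sits a fixed 45-day gap before its outcome date. Four controls
  per case are drawn from the case's date-of-birth partition by sampling
  *visits* uniformly among patients without an outcome event, over the span
  of case outcome dates in that partition; the sampled visit date becomes
  the control's pseudo-outcome date. Visit-weighted sampling deliberately
  over-represents heavy utilizers, matching cases and controls on both age
  and healthcare contact intensity.
- **Calendar prospective** (C15/C17/C19 analogues) — everyone with a visit
  in the lookback window before a fixed prediction date; outcomes counted
  in a follow-up window that excludes the first week after prediction.
- **Event-triggered time-to-event** (Cox-MH / Cox-Visit analogues) — time
  of prediction is the first qualifying psychiatric or office visit inside
  a three-year initiation window; follow-up is right-censored on death
  only, never on last visit, so patients who drop out of care stay in.

Date-of-birth partitioning splits patients into k (default 100) contiguous
DOB-ordered groups; partition parity defines the even/odd train/test halves
used by every model in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from riskpipe._dates import as_days, date_col, days_to_dates
from riskpipe.features import WINDOW_DAYS
from riskpipe.outcomes import SUICIDE, classify_events, build_outcome_table

DAYS_PER_MONTH = 365.25 / 12.0


class CohortShortfallError(RuntimeError):
    """Not enough eligible controls in a DOB partition; carries a report."""

    def __init__(self, report: pd.DataFrame):
        self.report = report
        super().__init__(f"control shortfall in {len(report)} partition(s):\n{report}")


@dataclass
class RccConfig:
    controls_per_case: int = 4
    gap_days: int = 45
    earliest_outcome_date: object = None  # default: calendar start + window + gap
    allow_control_reuse: bool = True      # across cases; never within one case's draw
    target: str = "combined"              # or "suicide"
    seed: int = 0

    def __post_init__(self):
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.gap_days < 0:
            raise ValueError("gap_days must be >= 0")


def assign_dob_partitions(patients: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Contiguous DOB-ordered partitions, sizes equal within one.

    Returns (patient_id, dob_partition, even) with partition 0 holding the
    oldest patients. Ties in DOB break by patient_id so the assignment is
    deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(patients) < k:
        raise ValueError(f"fewer patients ({len(patients)}) than partitions ({k})")
    order = patients.sort_values(["dob", "patient_id"], kind="stable")
    parts = np.concatenate([np.full(len(chunk), i)
                            for i, chunk in enumerate(np.array_split(np.arange(len(order)), k))])
    out = pd.DataFrame({"patient_id": order["patient_id"].to_numpy(),
                        "dob_partition": parts})
    out["even"] = out["dob_partition"] % 2 == 0
    return out.sort_values("patient_id").reset_index(drop=True)


def compute_outcomes(population, window=None) -> pd.DataFrame:
    """Classify the population's coded events and build per-patient combined
    outcomes over ``window`` (default: the full calendar range present)."""
    comp = classify_events(population.events, population.deaths)
    if window is None:
        lo = min(date_col(population.events["date"]).min(),
                 date_col(population.visits["date"]).min())
        hi = max(date_col(population.events["date"]).max(),
                 date_col(population.deaths["date"]).max()
                 if len(population.deaths) else 0) + 1
        window = (np.datetime64(int(lo), "D"), np.datetime64(int(hi), "D"))
    return build_outcome_table(comp, window)


def _component_events(population) -> pd.DataFrame:
    return classify_events(population.events, population.deaths)


def build_rcc(population, outcomes: pd.DataFrame, config: RccConfig,
              partitions: pd.DataFrame | None = None,
              calendar_range=None) -> pd.DataFrame:
    """Matched retrospective nested case-control cohort.

    ``outcomes`` is a per-patient combined-outcome table
    (:func:`compute_outcomes`). Cases are patients whose outcome (combined,
    or suicide only when ``config.target == "suicide"``) falls on or after
    ``earliest_outcome_date``; their time of prediction is ``gap_days``
    before the outcome. Controls are visit-weighted draws from the same DOB
    partition among patients with no outcome event, the sampled visit date
    serving as pseudo-outcome date, restricted to the span of case outcome
    dates in that partition.
    """
    rng = np.random.default_rng(config.seed)
    if partitions is None:
        partitions = assign_dob_partitions(
            population.patients, min(100, len(population.patients)))
    part_of = partitions.set_index("patient_id")["dob_partition"]

    if calendar_range is not None:
        cal_start = as_days(calendar_range[0])
    else:
        cal_start = date_col(population.visits["date"]).min()
    earliest = (as_days(config.earliest_outcome_date)
                if config.earliest_outcome_date is not None
                else cal_start + WINDOW_DAYS + config.gap_days)

    oc = outcomes.copy()
    if config.target == "suicide":
        oc = oc.loc[oc["component"] == SUICIDE]
    oc_days = date_col(oc["event_date"])
    cases = oc.loc[oc_days >= earliest].copy()
    cases["event_days"] = oc_days[oc_days >= earliest]
    cases["dob_partition"] = cases["patient_id"].map(part_of).to_numpy()

    with_outcome = set(outcomes["patient_id"])
    visits = population.visits
    v_pid = visits["patient_id"].to_numpy()
    v_day = date_col(visits["date"])
    eligible = ~np.isin(v_pid, list(with_outcome))
    v_pid, v_day = v_pid[eligible], v_day[eligible]
    v_part = pd.Series(v_pid).map(part_of).to_numpy()

    rows = []
    shortfalls = []
    for part, grp in cases.groupby("dob_partition"):
        span_lo, span_hi = grp["event_days"].min(), grp["event_days"].max()
        sel = (v_part == part) & (v_day >= span_lo) & (v_day <= span_hi) \
            & (v_day - config.gap_days - WINDOW_DAYS >= cal_start)
        pool_pid = v_pid[sel]
        pool_day = v_day[sel]
        pool_live = np.ones(len(pool_pid), dtype=bool)
        n_owners = len(np.unique(pool_pid))
        for _, case in grp.iterrows():
            chosen_pid, chosen_day = [], []
            avail = np.flatnonzero(pool_live)
            # draw visits until controls_per_case distinct owners are found
            tries = 0
            while len(chosen_pid) < config.controls_per_case and len(avail) and tries < 50:
                need = config.controls_per_case - len(chosen_pid)
                take = min(len(avail), max(need * 2, need))
                picks = rng.choice(avail, size=take, replace=False)
                for p in picks:
                    if pool_pid[p] not in chosen_pid:
                        chosen_pid.append(pool_pid[p])
                        chosen_day.append(pool_day[p])
                        if len(chosen_pid) == config.controls_per_case:
                            break
                avail = avail[~np.isin(pool_pid[avail], chosen_pid)]
                tries += 1
            if len(chosen_pid) < config.controls_per_case:
                shortfalls.append({"dob_partition": part, "case_id": case["patient_id"],
                                   "needed": config.controls_per_case,
                                   "found": len(chosen_pid),
                                   "eligible_owners": n_owners})
                continue
            if not config.allow_control_reuse:
                pool_live &= ~np.isin(pool_pid, chosen_pid)
            rows.append({"patient_id": case["patient_id"],
                         "time_of_prediction": case["event_days"] - config.gap_days,
                         "is_case": True, "component": case["component"],
                         "event_date": case["event_days"], "dob_partition": part})
            for cp, cd in zip(chosen_pid, chosen_day):
                rows.append({"patient_id": cp, "time_of_prediction": cd - config.gap_days,
                             "is_case": False, "component": "none",
                             "event_date": cd, "dob_partition": part})
    if shortfalls:
        raise CohortShortfallError(pd.DataFrame(shortfalls))
    out = pd.DataFrame(rows)
    if len(out):
        out["time_of_prediction"] = days_to_dates(out["time_of_prediction"].to_numpy())
        out["event_date"] = days_to_dates(out["event_date"].to_numpy())
        out["design_tag"] = "Rcc"
        out["even"] = out["dob_partition"] % 2 == 0
    return out.reset_index(drop=True)


def build_calendar_cohort(population, outcomes_or_events, prediction_date,
                          lookback_months: float = 3, exclusion_days: int = 7,
                          followup_years: float = 2, target: str = "combined",
                          partitions: pd.DataFrame | None = None,
                          design_tag: str = "calendar") -> pd.DataFrame:
    """Calendar prospective cohort (C15/C17/C19 analogue).

    Includes every patient with >= 1 visit in the ``lookback_months`` window
    before ``prediction_date`` and alive at it. Cases have their combined
    outcome (or suicide, per ``target``) strictly after the one-week
    exclusion and within the follow-up horizon. ``outcomes_or_events`` may
    be a classified component-event table or None (classified on the fly).
    """
    t = as_days(prediction_date)
    look = int(round(lookback_months * DAYS_PER_MONTH))
    fup = int(round(followup_years * 365.25))
    if partitions is None:
        partitions = assign_dob_partitions(
            population.patients, min(100, len(population.patients)))

    v_day = date_col(population.visits["date"])
    in_look = (v_day >= t - look) & (v_day < t)
    included = np.unique(population.visits["patient_id"].to_numpy()[in_look])

    if len(population.deaths):
        d_day = date_col(population.deaths["date"])
        dead_before = set(population.deaths["patient_id"].to_numpy()[d_day < t])
        included = np.array([p for p in included if p not in dead_before])

    comp = (outcomes_or_events if outcomes_or_events is not None
            else _component_events(population))
    window = (np.datetime64(t + exclusion_days + 1, "D"),
              np.datetime64(t + fup + 1, "D"))
    if target == "suicide":
        comp = comp.loc[comp["component"] == SUICIDE]
    oc = build_outcome_table(comp, window)
    oc = oc.set_index("patient_id")

    out = pd.DataFrame({"patient_id": included})
    out["time_of_prediction"] = np.datetime64(t, "D")
    out["component"] = out["patient_id"].map(oc["component"]).fillna("none")
    out["event_date"] = out["patient_id"].map(oc["event_date"])
    out["is_case"] = out["component"] != "none"
    out["dob_partition"] = out["patient_id"].map(
        partitions.set_index("patient_id")["dob_partition"])
    out["even"] = out["dob_partition"] % 2 == 0
    out["design_tag"] = design_tag
    return out


def build_event_cohort(population, outcomes_or_events=None,
                       trigger: str = "psychiatric-visit",
                       initiation_start=None, initiation_window_years: float = 3,
                       followup_years: float = 10, target: str = "combined",
                       partitions: pd.DataFrame | None = None,
                       calendar_range=None) -> pd.DataFrame:
    """Event-triggered time-to-event cohort (Cox-MH / Cox-Visit analogue).

    Time of prediction is each patient's first qualifying visit inside the
    initiation window (default: three years starting 7.5 y after calendar
    start, mirroring a mid-2007 start on data from 2000). Follow-up is
    right-censored on death only — never on last visit — so patients who
    drop out of care still contribute events. Returns rows with
    ``time_to_event_days`` and ``censored``; patients with no qualifying
    visit are excluded and counted in ``.attrs["n_excluded"]``.
    """
    vt = {"psychiatric-visit": "psych", "office-visit": "office"}.get(trigger)
    if vt is None:
        raise ValueError(f"unknown trigger {trigger!r}")
    if partitions is None:
        partitions = assign_dob_partitions(
            population.patients, min(100, len(population.patients)))
    v_day = date_col(population.visits["date"])
    if calendar_range is not None:
        cal_start = as_days(calendar_range[0])
        cal_end = as_days(calendar_range[1])
    else:
        cal_start = v_day.min()
        cal_end = v_day.max() + 1
    start = (as_days(initiation_start) if initiation_start is not None
             else cal_start + WINDOW_DAYS)
    stop = start + int(round(initiation_window_years * 365.25))

    is_trig = (population.visits["visit_type"] == vt).to_numpy()
    in_win = is_trig & (v_day >= start) & (v_day < stop)
    trig = pd.DataFrame({"patient_id": population.visits["patient_id"].to_numpy()[in_win],
                         "day": v_day[in_win]})
    first = trig.groupby("patient_id")["day"].min()
    n_excluded = population.patients["patient_id"].nunique() - len(first)

    comp = (outcomes_or_events if outcomes_or_events is not None
            else _component_events(population))
    if target == "suicide":
        comp = comp.loc[comp["component"] == SUICIDE]
    c_day = date_col(comp["date"]) if len(comp) else np.empty(0, dtype=np.int64)

    deaths = population.deaths.set_index("patient_id")
    death_day = pd.Series(date_col(population.deaths["date"]),
                          index=population.deaths["patient_id"]) if len(population.deaths) \
        else pd.Series(dtype="int64")

    rows = []
    comp_by_pid = {pid: grp for pid, grp in
                   pd.DataFrame({"patient_id": comp["patient_id"],
                                 "day": c_day,
                                 "component": comp["component"]}).groupby("patient_id")} \
        if len(comp) else {}
    fup = int(round(followup_years * 365.25))
    for pid, t in first.items():
        horizon = min(t + fup, cal_end)
        dd = death_day.get(pid, None)
        ev = comp_by_pid.get(pid)
        ev_day, ev_comp = None, "none"
        if ev is not None:
            after = ev.loc[(ev["day"] > t) & (ev["day"] <= horizon)]
            if len(after):
                i = after["day"].idxmin()
                ev_day = int(after.loc[i, "day"])
                ev_comp = after.loc[i, "component"]
        if ev_day is not None and (dd is None or ev_day <= dd):
            tte, censored = ev_day - t, False
        elif dd is not None and dd < horizon:
            tte, censored, ev_comp = dd - t, True, "none"
        else:
            tte, censored, ev_comp = horizon - t, True, "none"
        rows.append({"patient_id": pid, "time_of_prediction": t,
                     "is_case": not censored, "component": ev_comp,
                     "event_date": (t + tte) if not censored else None,
                     "time_to_event_days": int(tte), "censored": censored})
    out = pd.DataFrame(rows)
    if len(out):
        out["time_of_prediction"] = days_to_dates(out["time_of_prediction"].to_numpy())
        out["dob_partition"] = out["patient_id"].map(
            partitions.set_index("patient_id")["dob_partition"])
        out["even"] = out["dob_partition"] % 2 == 0
        out["design_tag"] = "CoxMH" if vt == "psych" else "CoxVisit"
    out.attrs["n_excluded"] = int(n_excluded)
    return out
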