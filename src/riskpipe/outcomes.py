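"""Outcome classification and the combined-outcome priority rule.

Three component outcomes are recognized from coded diagnosis / cause-of-death
records: death by suicide, suicide attempt, and drug overdose. Suicide-related
codes are matched with one family of anchored regular expressions (ICD-9
``^e95``; ICD-10 ``^T14.91``, ``^T3[6789]..X2``, ``^T[456]..X2``,
``^X[678]..XX``, ``^Y87.0``); the record context decides whether a match means
*suicide* (cause-of-death record) or *attempt* (clinical record). Overdoses
are matched with ``^e850``, ``^e8[67]``, ``^e935`` (ICD-9) and ``^T40``
(ICD-10). Matching is case-insensitive because ICD-9 external-cause codes are
conventionally written upper-case while the pattern family is lower-case.

The combined outcome for a patient in a study window is built by priority:
a suicide death anywhere in the window wins; otherwise the earliest suicide
attempt; otherwise the earliest overdose; otherwise no outcome. Each patient
contributes at most one case event per window, so patients with many attempts
are not counted repeatedly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskpipe._dates import as_days, date_col

SUICIDE = "suicide"
ATTEMPT = "attempt"
OVERDOSE = "overdose"
NONE = "none"

COMPONENTS = (SUICIDE, ATTEMPT, OVERDOSE)

#: priority order of components when building the combined outcome
PRIORITY = {SUICIDE: 0, ATTEMPT: 1, OVERDOSE: 2}

_SUICIDE_ICD9 = ["^e95"]
_SUICIDE_ICD10 = ["^T14.91", "^T3[6789]..X2", "^T[456]..X2", "^X[678]..XX", "^Y87.0"]
_OVERDOSE_ICD9 = ["^e850", "^e8[67]", "^e935"]
_OVERDOSE_ICD10 = ["^T40"]


@dataclass(frozen=True)
class CodePatternSet:
    """Anchored regex families mapping ICD codes to outcome components.

    ``component`` is ``"suicide-related"`` or ``"overdose"``. Suicide-related
    matches are contextual: a cause-of-death record yields *suicide*, a
    clinical record yields *attempt*.
    """

    component: str
    icd9_patterns: tuple = ()
    icd10_patterns: tuple = ()

    def __post_init__(self):
        for p in (*self.icd9_patterns, *self.icd10_patterns):
            if not p.startswith("^"):
                raise ValueError(f"pattern {p!r} must be anchored at string start")

    def compiled(self, code_system: str) -> re.Pattern:
        pats = {"ICD9": self.icd9_patterns, "ICD10": self.icd10_patterns}[code_system]
        if not pats:
            return re.compile(r"(?!)")  # never matches
        return re.compile("|".join(f"(?:{p})" for p in pats), re.IGNORECASE)


SUICIDE_RELATED_PATTERNS = CodePatternSet(
    "suicide-related", tuple(_SUICIDE_ICD9), tuple(_SUICIDE_ICD10)
)
OVERDOSE_PATTERNS = CodePatternSet("overdose", tuple(_OVERDOSE_ICD9), tuple(_OVERDOSE_ICD10))

DEFAULT_PATTERNS = (SUICIDE_RELATED_PATTERNS, OVERDOSE_PATTERNS)


@dataclass(frozen=True)
class OutcomeLabel:
    """Per-patient combined outcome for one study window."""

    patient_id: object
    component: str  # suicide | attempt | overdose | none
    event_date: object = None  # np.datetime64[D] or None
    rule_applied: str = "no-event"

    def __post_init__(self):
        if (self.component == NONE) != (self.event_date is None):
            raise ValueError("component=none iff event_date is null")


def _check_system(code_system: str) -> str:
    cs = str(code_system).upper().replace("-", "")
    if cs not in ("ICD9", "ICD10"):
        raise ValueError(f"unknown code system {code_system!r}")
    return cs


def classify_code(code: str, code_system: str, context: str = "clinical",
                  patterns=DEFAULT_PATTERNS) -> str:
    """Classify one ICD code into a component.

    Parameters
    ----------
    code : str
        Non-empty ICD code string, e.g. ``"T14.91"`` or ``"E9509"``.
    code_system : {"ICD9", "ICD10"}
    context : {"clinical", "death-cause"}
        Suicide-related matches map to *suicide* in cause-of-death records
        and to *attempt* in clinical records.

    Returns
    -------
    str
        One of ``"suicide"``, ``"attempt"``, ``"overdose"``, ``"none"``.
    """
    if not code:
        raise ValueError("empty code")
    cs = _check_system(code_system)
    if context not in ("clinical", "death-cause"):
        raise ValueError(f"unknown context {context!r}")
    suicide_related, overdose = patterns
    if suicide_related.compiled(cs).match(code):
        return SUICIDE if context == "death-cause" else ATTEMPT
    # overdoses are sourced from clinical diagnosis records only
    if context == "clinical" and overdose.compiled(cs).match(code):
        return OVERDOSE
    return NONE


def classify_events(events: pd.DataFrame, deaths: pd.DataFrame | None = None,
                    patterns=DEFAULT_PATTERNS) -> pd.DataFrame:
    """Classify coded clinical events and death records into component events.

    ``events`` needs columns (patient_id, date, code, code_system); ``deaths``
    needs (patient_id, date, cause_codes) where cause_codes is a
    semicolon-separated list carrying underlying and contributing causes,
    each optionally suffixed ``|ICD9``/``|ICD10`` (default ICD10).

    Returns a long table (patient_id, date, component, source) restricted to
    rows that matched a component, sorted by (patient_id, date); within a
    patient, the original record order is preserved for ties so downstream
    tie-breaks are deterministic.
    """
    suicide_related, overdose = patterns
    frames = []
    if len(events):
        ev = events.reset_index(drop=True)
        comp = np.full(len(ev), NONE, dtype=object)
        for cs in ("ICD9", "ICD10"):
            m = (ev["code_system"].str.upper().str.replace("-", "", regex=False) == cs).to_numpy()
            if not m.any():
                continue
            codes = ev.loc[m, "code"].astype(str)
            sui = codes.str.match(suicide_related.compiled(cs)).to_numpy()
            od = codes.str.match(overdose.compiled(cs)).to_numpy()
            sub = np.full(m.sum(), NONE, dtype=object)
            sub[od] = OVERDOSE
            sub[sui] = ATTEMPT  # clinical context; suicide family wins over overdose
            comp[m] = sub
        keep = comp != NONE
        if keep.any():
            frames.append(pd.DataFrame({
                "patient_id": ev.loc[keep, "patient_id"].to_numpy(),
                "date": pd.to_datetime(ev.loc[keep, "date"]).to_numpy().astype("datetime64[D]"),
                "component": comp[keep],
                "source": "clinical",
            }))
    if deaths is not None and len(deaths):
        rows = []
        for _, r in deaths.iterrows():
            for tok in str(r["cause_codes"]).split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                code, _, cs = tok.partition("|")
                cs = cs or "ICD10"
                comp = classify_code(code, cs, "death-cause", patterns)
                if comp == SUICIDE:
                    rows.append((r["patient_id"], np.datetime64(pd.Timestamp(r["date"]).date(), "D")))
                    break  # one suicide death per patient
        if rows:
            frames.append(pd.DataFrame({
                "patient_id": [r[0] for r in rows],
                "date": [r[1] for r in rows],
                "component": SUICIDE,
                "source": "death-cause",
            }))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "date", "component", "source"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    return out


def build_combined_outcome(component_events: pd.DataFrame,
                           allowed_window: tuple) -> OutcomeLabel:
    """Combined outcome for one patient from classified component events.

    Priority inside the half-open window ``[start, end)``: any suicide death
    wins (its own date is kept); else the earliest attempt; else the earliest
    overdose; else none. Same-date ties across components resolve by priority
    order; ties within a component take the earlier input record, so the
    result is independent of input row order.
    """
    start, end = (as_days(allowed_window[0]), as_days(allowed_window[1]))
    if end < start:
        raise ValueError("window end before start")
    ev = component_events
    pid = ev["patient_id"].iloc[0] if len(ev) else None
    if len(ev):
        if ev["patient_id"].nunique() > 1:
            raise ValueError("build_combined_outcome expects one patient's events")
        days = date_col(ev["date"])
        inwin = (days >= start) & (days < end)
        ev = ev.loc[inwin]
        days = days[inwin]
    if not len(ev):
        return OutcomeLabel(pid, NONE, None, "no-event")
    comp_order = ev["component"].map(PRIORITY).to_numpy()
    for comp, rule in ((SUICIDE, "suicide-in-window"),
                       (ATTEMPT, "first-attempt"),
                       (OVERDOSE, "first-overdose")):
        sel = comp_order == PRIORITY[comp]
        if sel.any():
            d = days[sel].min()
            return OutcomeLabel(ev["patient_id"].iloc[0], comp,
                                np.datetime64(int(d), "D"), rule)
    return OutcomeLabel(ev["patient_id"].iloc[0], NONE, None, "no-event")


def build_outcome_table(component_events: pd.DataFrame,
                        allowed_window: tuple) -> pd.DataFrame:
    """Vectorized combined outcome for all patients in a component-event table.

    Returns (patient_id, component, event_date, rule_applied), one row per
    patient that has at least one in-window component event.
    """
    start, end = (as_days(allowed_window[0]), as_days(allowed_window[1]))
    if end < start:
        raise ValueError("window end before start")
    if not len(component_events):
        return pd.DataFrame(columns=["patient_id", "component", "event_date", "rule_applied"])
    ev = component_events.copy()
    days = date_col(ev["date"])
    ev = ev.loc[(days >= start) & (days < end)].copy()
    if not len(ev):
        return pd.DataFrame(columns=["patient_id", "component", "event_date", "rule_applied"])
    ev["_prio"] = ev["component"].map(PRIORITY)
    ev["_days"] = date_col(ev["date"])
    # best component per patient = min priority; then earliest date within it
    best = ev.groupby("patient_id")["_prio"].transform("min")
    ev = ev.loc[ev["_prio"] == best]
    idx = ev.groupby("patient_id")["_days"].idxmin()
    out = ev.loc[idx, ["patient_id", "component", "_days"]].copy()
    out["event_date"] = out["_days"].astype("int64").to_numpy().astype("datetime64[D]")
    out["rule_applied"] = out["component"].map({
        SUICIDE: "suicide-in-window", ATTEMPT: "first-attempt", OVERDOSE: "first-overdose"})
    return out[["patient_id", "component", "event_date", "rule_applied"]].reset_index(drop=True)
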