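"""8-time-bin longitudinal feature encoding.

Every study design shares one observation-window layout: eight contiguous
half-open time bins ending at the row's time of prediction, widening
log-style into the past — two periods of three months, two of six months,
two of one year, and two of two years, 7.5 years in total. Binary coded
variables (diagnoses, medications, procedures, prior attempt/overdose codes)
are presence/absence per (variable, bin); labs and vitals are categorical
levels per bin with carry-forward-then-backward imputation and a dedicated
NA level used only when a patient has no measurement in the whole window;
PHQ surveys are score-band categoricals with a never-surveyed NA level;
demographics are cross-sectional. Months are fixed at 365.25/12 days so bin
boundaries are exact integer day offsets, identical for every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskpipe._dates import as_days, date_col

N_BINS = 8
#: bin widths in months, most recent first
BIN_WIDTHS_MONTHS = (3, 3, 6, 6, 12, 12, 24, 24)
#: cumulative day offsets back from the time of prediction (month = 365.25/12 d)
BIN_EDGES_DAYS = (0, 91, 183, 365, 548, 913, 1278, 2009, 2739)
WINDOW_DAYS = BIN_EDGES_DAYS[-1]


class LeakageError(RuntimeError):
    """An event dated at or after the time of prediction reached the encoder."""


@dataclass(frozen=True)
class BinSchedule:
    """Eight half-open date intervals ending at ``time_of_prediction``.

    Bin ``b`` covers days ``[t - edges[b+1], t - edges[b])``; bin 0 is the
    most recent. An event exactly on a boundary belongs to the more recent
    bin by the half-open convention.
    """

    time_of_prediction: int  # days since epoch
    edges: tuple = BIN_EDGES_DAYS

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def intervals(self):
        """List of (start_day, end_day) half-open intervals, bin 0 first."""
        t = self.time_of_prediction
        return [(t - self.edges[b + 1], t - self.edges[b]) for b in range(self.n_bins)]

    def bin_of(self, dates) -> np.ndarray:
        """Bin index per date; -1 for dates outside the 7.5-year window.

        Raises :class:`LeakageError` for any date >= time of prediction.
        """
        days = _as_day_array(dates)
        delta = self.time_of_prediction - days
        if (delta <= 0).any():
            bad = days[delta <= 0]
            raise LeakageError(
                f"{len(bad)} event(s) dated at/after time of prediction "
                f"(day {self.time_of_prediction})")
        b = np.searchsorted(self.edges, delta, side="left") - 1
        b[delta > self.edges[-1]] = -1
        return b


def _as_day_array(dates) -> np.ndarray:
    arr = np.asarray(dates)
    if arr.dtype.kind == "M":
        return arr.astype("datetime64[D]").astype("int64")
    if arr.dtype.kind in "iu":
        return arr.astype("int64")
    return pd.to_datetime(pd.Series(arr)).values.astype("datetime64[D]").astype("int64")


def make_time_bins(time_of_prediction) -> BinSchedule:
    """Build the shared 8-bin schedule ending at ``time_of_prediction``."""
    return BinSchedule(as_days(time_of_prediction))


def encode_binary(events: pd.DataFrame, schedule: BinSchedule,
                  variable_list) -> np.ndarray:
    """Presence/absence block for one row: shape (n_variables, 8), uint8.

    ``events`` holds one row's events (columns variable, date); any event
    dated at/after the time of prediction is a hard leakage failure. Events
    older than the window are ignored. Cell (v, b) is 1 iff at least one
    event of variable v falls in bin b.
    """
    variable_list = list(variable_list)
    out = np.zeros((len(variable_list), schedule.n_bins), dtype=np.uint8)
    if not len(events):
        return out
    bins = schedule.bin_of(events["date"])
    vidx = pd.Index(variable_list).get_indexer(events["variable"])
    keep = (bins >= 0) & (vidx >= 0)
    out[vidx[keep], bins[keep]] = 1
    return out


@dataclass
class FeatureMatrix:
    """Row-aligned design matrix with column metadata.

    ``X`` is dense float64, rows aligned with ``cohort`` rows. ``meta`` maps
    each column to (variable, bin, level, block); bin is -1 for
    cross-sectional columns, level is "" for binary indicators. ``dx_mask``
    marks the diagnosis-variable binary columns that define the utilization
    index.
    """

    X: np.ndarray
    meta: pd.DataFrame
    cohort: pd.DataFrame
    schedule_edges: tuple = BIN_EDGES_DAYS

    @property
    def columns(self):
        return self.meta["column"].tolist()

    def block(self, name: str) -> np.ndarray:
        return self.X[:, (self.meta["block"] == name).to_numpy()]

    def dx_binary(self) -> np.ndarray:
        m = ((self.meta["block"] == "binary") & self.meta["is_dx"]).to_numpy()
        return self.X[:, m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def compute_utilization(dx_block: np.ndarray) -> np.ndarray:
    """Utilization index: count of active (diagnosis variable, bin) cells.

    With the default 75 diagnosis variables and 8 bins the range is
    0..600. Accepts a (rows, 75*8) block or a single row.
    """
    arr = np.atleast_2d(np.asarray(dx_block))
    return arr.sum(axis=1).astype(np.int64)


def _impute_levels(per_bin: np.ndarray) -> np.ndarray:
    """Carry levels forward in time (old->recent) then backward. -1 = missing.

    Bin 0 is most recent, so chronological forward fill runs from high bin
    index to low.
    """
    out = per_bin.copy()
    n = len(out)
    # forward in time: bin n-1 (oldest) -> bin 0
    for b in range(n - 2, -1, -1):
        if out[b] < 0 <= out[b + 1]:
            out[b] = out[b + 1]
    # backward in time: bin 0 -> bin n-1
    for b in range(1, n):
        if out[b] < 0 <= out[b - 1]:
            out[b] = out[b - 1]
    return out


@dataclass(frozen=True)
class LabSpec:
    """Categorical encoding of one lab/vital: ordered boundaries and levels.

    ``boundaries`` of length k split the real line into k+1 levels named by
    ``levels`` (low to high); ``reference`` names the dropped level.
    """

    name: str
    boundaries: tuple
    levels: tuple
    reference: str = "normal"

    def __post_init__(self):
        if len(self.levels) != len(self.boundaries) + 1:
            raise ValueError(f"{self.name}: need len(levels) == len(boundaries)+1")
        if self.reference not in self.levels:
            raise ValueError(f"{self.name}: reference {self.reference!r} not a level")

    def level_of(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.boundaries), np.asarray(values, dtype=float),
                               side="right")

    @property
    def coded_levels(self):
        """Levels that get indicator columns (non-reference), plus 'NA'."""
        return [lv for lv in self.levels if lv != self.reference] + ["NA"]


#: pulse pressure (systolic - diastolic, mm Hg): <30, 30-50 reference, 50-70, >70
PULSE_PRESSURE_SPEC = LabSpec("pulse_pressure", (30.0, 50.0, 70.0),
                              ("low", "normal", "high", "very_high"), "normal")

DEFAULT_LAB_SPECS = (
    PULSE_PRESSURE_SPEC,
    LabSpec("hemoglobin", (8.0, 12.0, 16.0, 18.0),
            ("very_low", "low", "normal", "high", "very_high"), "normal"),
    LabSpec("a1c", (5.7, 6.5), ("normal", "high", "very_high"), "normal"),
    LabSpec("egfr", (30.0, 60.0, 90.0), ("very_low", "low", "normal", "normal_hi"),
            "normal"),
)

#: PHQ score bands (low band is the reference); item 9 is its own variable
PHQ_SPECS = (
    LabSpec("phq2_total", (3.0,), ("low", "high"), "low"),
    LabSpec("phq9_total", (5.0, 10.0, 15.0, 20.0),
            ("low", "mild", "moderate", "mod_severe", "severe"), "low"),
    LabSpec("phq9_item9", (1.0, 2.0), ("low", "some", "high"), "low"),
)

PHQ_RANGES = {"phq2_total": (0, 6), "phq9_total": (0, 27), "phq9_item9": (0, 3)}


def encode_lab(measurements: pd.DataFrame, schedule: BinSchedule,
               spec: LabSpec) -> np.ndarray:
    """One row's categorical block for one lab: (len(coded_levels), 8) uint8.

    Per bin, the latest in-bin measurement sets the level; missing bins are
    imputed carry-forward over time, then carry-backward. The NA level is set
    in all bins only when the patient has no measurement in the whole window.
    Exactly one of {non-reference indicators, NA} is active per bin unless
    the bin resolves to the reference level (all zeros).
    """
    coded = spec.coded_levels
    out = np.zeros((len(coded), schedule.n_bins), dtype=np.uint8)
    vals = pd.to_numeric(measurements["value"], errors="raise").to_numpy(dtype=float) \
        if len(measurements) else np.empty(0)
    per_bin = np.full(schedule.n_bins, -1, dtype=np.int64)
    if len(measurements):
        bins = schedule.bin_of(measurements["date"])
        days = _as_day_array(measurements["date"])
        keep = bins >= 0
        if keep.any():
            lv = spec.level_of(vals[keep])
            order = np.argsort(days[keep], kind="stable")  # latest-in-bin wins
            for i in order:
                per_bin[bins[keep][i]] = lv[i]
    if (per_bin < 0).all():
        out[coded.index("NA"), :] = 1
        return out
    per_bin = _impute_levels(per_bin)
    level_names = [spec.levels[i] for i in per_bin]
    for b, name in enumerate(level_names):
        if name != spec.reference:
            out[coded.index(name), b] = 1
    return out


def encode_surveys(phq_records: pd.DataFrame, schedule: BinSchedule,
                   specs=PHQ_SPECS) -> dict:
    """One row's PHQ blocks: {survey name -> (len(coded_levels), 8) uint8}.

    Total scores and the answer to question 9 are separate variables. Scores
    outside the instrument range raise. Never-surveyed windows get the NA
    level in all bins; the lowest band is the reference.
    """
    out = {}
    for spec in specs:
        sub = phq_records.loc[phq_records["lab"] == spec.name] if len(phq_records) \
            else phq_records
        if len(sub):
            lo, hi = PHQ_RANGES[spec.name]
            v = pd.to_numeric(sub["value"], errors="raise")
            if ((v < lo) | (v > hi)).any():
                raise ValueError(f"{spec.name} score outside range [{lo}, {hi}]")
        out[spec.name] = encode_lab(sub, schedule, spec)
    return out


def pulse_pressure_records(labs: pd.DataFrame) -> pd.DataFrame:
    """Derive pulse-pressure measurements (systolic - diastolic, same date)."""
    sys = labs.loc[labs["lab"] == "systolic", ["patient_id", "date", "value"]]
    dia = labs.loc[labs["lab"] == "diastolic", ["patient_id", "date", "value"]]
    m = sys.merge(dia, on=["patient_id", "date"], suffixes=("_s", "_d"))
    out = m[["patient_id", "date"]].copy()
    out["lab"] = "pulse_pressure"
    out["value"] = m["value_s"].astype(float) - m["value_d"].astype(float)
    return out


DEMOGRAPHIC_REFERENCES = {"sex": "M", "race": "white", "ethnicity": "non_hispanic"}


def encode_cohort(cohort: pd.DataFrame, population, variable_list=None,
                  lab_specs=DEFAULT_LAB_SPECS, phq_specs=PHQ_SPECS,
                  include_labs: bool = True, include_surveys: bool = True,
                  include_demographics: bool = True) -> FeatureMatrix:
    """Encode every cohort row into the shared 8-bin design matrix.

    ``cohort`` needs (patient_id, time_of_prediction); rows may repeat a
    patient (Rcc controls). Events at/after a row's time of prediction are
    simply outside its observation window — windowing here is what prevents
    leakage, and :func:`riskpipe.metrics.leakage_audit` verifies it by brute
    force. Demographic categoricals are reference-coded with missing values
    kept as their own level; age (decades, centered at 55) and the synthetic
    area covariate enter once as continuous columns.
    """
    events = population.events
    labs = population.labs
    patients = population.patients.set_index("patient_id")
    if variable_list is None:
        variable_list = population.variable_list
    variable_list = list(variable_list)
    dx_set = set(population.dx_variables) if hasattr(population, "dx_variables") else set()

    n = len(cohort)
    t_row = _as_day_array(cohort["time_of_prediction"])
    row_of_patient = pd.DataFrame({
        "row": np.arange(n),
        "patient_id": cohort["patient_id"].to_numpy(),
        "t": t_row,
    })

    nvar = len(variable_list)
    bin_block = np.zeros((n, nvar * N_BINS), dtype=np.float64)
    ev = events.merge(row_of_patient, on="patient_id", how="inner")
    if len(ev):
        d = _as_day_array(ev["date"])
        delta = ev["t"].to_numpy() - d
        inwin = (delta > 0) & (delta <= WINDOW_DAYS)
        ev = ev.loc[inwin]
        delta = delta[inwin]
        b = np.searchsorted(BIN_EDGES_DAYS, delta, side="left") - 1
        vidx = pd.Index(variable_list).get_indexer(ev["variable"])
        keep = vidx >= 0
        cols = vidx[keep] * N_BINS + b[keep]
        bin_block[ev["row"].to_numpy()[keep], cols] = 1.0

    meta_rows = [{"column": f"{v}__bin{b}", "variable": v, "bin": b, "level": "",
                  "block": "binary", "is_dx": v in dx_set}
                 for v in variable_list for b in range(N_BINS)]
    blocks = [bin_block]

    if include_labs:
        lab_records = labs
        specs = list(lab_specs)
        if any(s.name == "pulse_pressure" for s in specs):
            pp = pulse_pressure_records(labs)
            lab_records = pd.concat([labs, pp], ignore_index=True)
        for spec in specs:
            blk, meta = _encode_lab_block(lab_records, row_of_patient, n, spec)
            blocks.append(blk)
            meta_rows.extend(meta)
    if include_surveys:
        for spec in phq_specs:
            sub = labs.loc[labs["lab"] == spec.name]
            if len(sub):
                lo, hi = PHQ_RANGES[spec.name]
                v = pd.to_numeric(sub["value"], errors="raise")
                if ((v < lo) | (v > hi)).any():
                    raise ValueError(f"{spec.name} score outside range [{lo}, {hi}]")
            blk, meta = _encode_lab_block(labs, row_of_patient, n, spec)
            blocks.append(blk)
            meta_rows.extend(meta)

    if include_demographics:
        demo = patients.reindex(cohort["patient_id"].to_numpy())
        dob = _as_day_array(demo["dob"])
        age_dec = (t_row - dob) / 365.25 / 10.0
        blocks.append((age_dec - 5.5).reshape(-1, 1))
        meta_rows.append({"column": "age_decades_c", "variable": "age", "bin": -1,
                          "level": "", "block": "demographic", "is_dx": False})
        if "area_deprivation" in demo.columns:
            blocks.append(demo["area_deprivation"].to_numpy(dtype=float).reshape(-1, 1))
            meta_rows.append({"column": "area_deprivation", "variable": "area_deprivation",
                              "bin": -1, "level": "", "block": "demographic",
                              "is_dx": False})
        for var, ref in DEMOGRAPHIC_REFERENCES.items():
            vals = demo[var].astype(str).fillna("missing")
            for lv in sorted(set(vals) - {ref}):
                blocks.append((vals == lv).to_numpy(dtype=float).reshape(-1, 1))
                meta_rows.append({"column": f"{var}__{lv}", "variable": var, "bin": -1,
                                  "level": lv, "block": "demographic", "is_dx": False})

    X = np.hstack(blocks)
    meta = pd.DataFrame(meta_rows)
    assert X.shape[1] == len(meta)
    return FeatureMatrix(X=X, meta=meta, cohort=cohort.reset_index(drop=True))


def _encode_lab_block(lab_records, row_of_patient, n, spec):
    """Vectorized categorical block for one lab over all rows."""
    coded = spec.coded_levels
    ncod = len(coded)
    blk = np.zeros((n, ncod * N_BINS), dtype=np.float64)
    sub = lab_records.loc[lab_records["lab"] == spec.name]
    merged = sub.merge(row_of_patient, on="patient_id", how="inner") if len(sub) else sub
    per_bin = np.full((n, N_BINS), -1, dtype=np.int64)
    if len(merged):
        d = _as_day_array(merged["date"])
        delta = merged["t"].to_numpy() - d
        inwin = (delta > 0) & (delta <= WINDOW_DAYS)
        merged = merged.loc[inwin]
        if len(merged):
            d = d[inwin]
            delta = delta[inwin]
            b = np.searchsorted(BIN_EDGES_DAYS, delta, side="left") - 1
            lv = spec.level_of(pd.to_numeric(merged["value"], errors="raise").to_numpy())
            rows = merged["row"].to_numpy()
            order = np.argsort(d, kind="stable")  # latest measurement in a bin wins
            per_bin[rows[order], b[order]] = lv[order]
    has_any = (per_bin >= 0).any(axis=1)
    # vectorized forward (old->recent) then backward fill across bins
    filled = per_bin.astype(float)
    filled[filled < 0] = np.nan
    df = pd.DataFrame(filled[:, ::-1])  # chronological order
    df = df.ffill(axis=1).bfill(axis=1)
    filled = df.to_numpy()[:, ::-1]
    na_idx = coded.index("NA")
    ref_idx = spec.levels.index(spec.reference)
    level_to_col = {i: (coded.index(lv) if lv != spec.reference else -1)
                    for i, lv in enumerate(spec.levels)}
    for b in range(N_BINS):
        col_lv = filled[:, b]
        for lvi, ci in level_to_col.items():
            if ci < 0:
                continue
            m = has_any & (col_lv == lvi)
            blk[m, ci * N_BINS + b] = 1.0
        blk[~has_any, na_idx * N_BINS + b] = 1.0
    _ = ref_idx
    meta = [{"column": f"{spec.name}__{lv}__bin{b}", "variable": spec.name, "bin": b,
             "level": lv, "block": "lab", "is_dx": False}
            for lv in coded for b in range(N_BINS)]
    return blk, meta


FINETUNE_NAMES = ("female", "nonwhite_race", "hispanic", "young_lt55", "old_gt65",
                  "chronic_pain", "suicide_ideation", "suicide_attempt", "overdose",
                  "usage")


def aggregate_finetune(fm: FeatureMatrix, population) -> pd.DataFrame:
    """The ten design-sensitive fine-tuning covariates, one row per cohort row.

    Nine binary indicators — sex (female), race (non-white), ethnicity
    (Hispanic), age under 55, age over 65, and any-bin presence of chronic
    pain, suicide ideation, suicide attempt and overdose codes over the 7.5
    year window — plus the raw utilization index (0..600). Presence in any
    time bin counts as present.
    """
    patients = population.patients.set_index("patient_id")
    demo = patients.reindex(fm.cohort["patient_id"].to_numpy())
    t_row = _as_day_array(fm.cohort["time_of_prediction"])
    age = (t_row - _as_day_array(demo["dob"])) / 365.25

    def any_bin(varname):
        m = ((fm.meta["block"] == "binary") & (fm.meta["variable"] == varname)).to_numpy()
        if not m.any():
            return np.zeros(len(fm.cohort))
        return (fm.X[:, m].sum(axis=1) > 0).astype(float)

    usage = compute_utilization(fm.dx_binary()).astype(float)
    out = pd.DataFrame({
        "female": (demo["sex"].astype(str) == "F").to_numpy(dtype=float),
        "nonwhite_race": (demo["race"].astype(str) != "white").to_numpy(dtype=float),
        "hispanic": (demo["ethnicity"].astype(str) == "hispanic").to_numpy(dtype=float),
        "young_lt55": (age < 55).astype(float),
        "old_gt65": (age > 65).astype(float),
        "chronic_pain": any_bin("chronic_pain"),
        "suicide_ideation": any_bin("suicide_ideation"),
        "suicide_attempt": any_bin("suicide_attempt"),
        "overdose": any_bin("overdose"),
        "usage": usage,
    })
    return out
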