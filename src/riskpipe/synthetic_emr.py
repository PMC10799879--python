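"""Seeded synthetic EMR populations with a known generating risk model.

The generator emulates a longitudinal health-record database: patients with
dates of birth spanning decades, a heavy-tailed per-patient visit process
over calendar years 2000-2021, ~75 binary diagnosis-coded variables plus
medications, labs/vitals, PHQ surveys and demographics, recurrent suicide
attempt / overdose events and an at-most-once suicide death drawn from a
known discrete-time logistic hazard that depends on the patient's trailing
feature state, age and visit intensity. Because the hazard includes a
positive utilization effect, confounding by healthcare contact intensity is
present by construction — the same confounding the matched case-control
design downstream must absorb.

Mechanics: each patient draws a yearly visit intensity from a log-normal
distribution and yearly visit counts from a Poisson with that intensity.
Each coded variable is emitted per visit with a fixed per-variable
probability. Once per calendar year the three outcome hazards are evaluated
on the trailing 8-year presence state (a yearly-resolution analogue of the
8-bin encoding the pipeline estimates), and Bernoulli draws decide events.
Suicide is terminal and unique; attempts and overdoses recur and are written
back into the event stream, so prior attempts raise future risk. Attempt,
overdose and suicide-death records carry real ICD-9/ICD-10 codes (system
chosen by date around the October 2015 changeover) so the regex outcome
classifier downstream is genuinely exercised; ordinary variables carry
representative non-matching codes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from riskpipe._dates import as_days, days_to_dates

COMPONENTS = ("suicide", "attempt", "overdose")


class ConfigurationError(ValueError):
    pass


class ProvenanceError(ValueError):
    """The population was not generated by the given config."""


# ---------------------------------------------------------------------------
# configuration

def default_dx_names(n: int) -> list:
    named = ["suicide_ideation", "chronic_pain", "depression", "substance_use",
             "anxiety", "ptsd", "bipolar", "schizophrenia", "homelessness",
             "tbi", "metastatic_cancer", "falls", "cvd", "copd", "diabetes"]
    if n < len(named):
        return named[:n]
    return named + [f"dx_{i:03d}" for i in range(n - len(named))]


def default_med_names(n: int) -> list:
    named = ["antidepressant_rx", "anxiolytic_rx", "opioid_rx", "antipsychotic_rx",
             "psychotherapy_cpt"]
    if n < len(named):
        return named[:n]
    return named + [f"med_{i:02d}" for i in range(n - len(named))]


#: representative ICD code pairs (ICD9, ICD10) for outcome events
ATTEMPT_CODES_ICD9 = ("E9509", "E9540", "E9580")
ATTEMPT_CODES_ICD10 = ("T14.91", "T39.1X2A", "X788XXA")
SUICIDE_DEATH_CODES_ICD9 = ("E9502", "E9530", "E9570")
SUICIDE_DEATH_CODES_ICD10 = ("T14.91", "X788XXA", "Y87.0")
OVERDOSE_CODES_ICD9 = ("E8502", "E8609", "E9350")
OVERDOSE_CODES_ICD10 = ("T40.2X1A", "T40.1X4A", "T40.4X1A")
NONSUICIDE_DEATH_CODES = ("I21.9", "C34.90", "J44.1")


@dataclass
class TrueRiskModel:
    """The generating hazard: per-component intercepts and log-odds effects.

    ``coefficients[comp][var]`` is the log-odds contribution of variable
    ``var`` being present in the trailing 8-year window; ``age_effect`` is
    log-odds per decade of age (centered at 55 y); ``utilization_effect`` is
    log-odds per active (variable, year) cell in the trailing window, the
    built-in confounding by healthcare contact. ``recurrence[comp]`` allows
    repeat events; suicide is always terminal and unique.
    """

    intercepts: dict = field(default_factory=lambda: {
        "suicide": -9.3, "attempt": -7.0, "overdose": -7.3})
    coefficients: dict = field(default_factory=lambda: {
        "suicide": {"suicide_ideation": 1.6, "depression": 0.7, "substance_use": 0.6,
                    "chronic_pain": 0.3, "suicide_attempt": 1.2},
        "attempt": {"suicide_ideation": 1.8, "depression": 0.9, "substance_use": 0.8,
                    "chronic_pain": 0.4, "suicide_attempt": 1.0},
        "overdose": {"substance_use": 1.6, "opioid_rx": 1.0, "chronic_pain": 0.6,
                     "overdose": 1.0},
    })
    age_effect: float = -0.15
    utilization_effect: float = 0.01
    recurrence: dict = field(default_factory=lambda: {
        "suicide": False, "attempt": True, "overdose": True})

    def __post_init__(self):
        if self.recurrence.get("suicide", False):
            raise ConfigurationError("suicide cannot recur")


def intercept_for_prevalence(target: float, n_years: int) -> float:
    """Intercept giving overall prevalence ``target`` over ``n_years`` annual
    Bernoulli trials when all other effects are zero."""
    if not 0 < target < 1:
        raise ConfigurationError("target prevalence must be in (0,1)")
    h = 1.0 - (1.0 - target) ** (1.0 / n_years)
    return float(np.log(h / (1.0 - h)))


@dataclass
class PopulationConfig:
    """Knobs of the synthetic population; defaults are the reference
    conditions used throughout the package's tests and examples."""

    n_patients: int = 10_000
    dob_range: tuple = ("1930-01-01", "1986-01-01")
    calendar_range: tuple = ("2000-01-01", "2022-01-01")
    n_dx_variables: int = 75
    n_med_variables: int = 15
    visit_rate_median: float = 2.5   # visits/year, log-normal across patients
    visit_rate_sigma: float = 0.8
    dx_prevalence: object = None     # per-visit emission prob per dx variable
    med_prevalence: object = None
    psych_visit_prob: float = 0.15   # StopCode-502-like visit tag
    office_visit_prob: float = 0.55  # StopCode-323-like visit tag
    lab_measure_prob: float = 0.35   # per-visit chance a lab panel is taken
    survey_prob: float = 0.35        # per-psych-visit chance of a PHQ survey
    icd_switch_date: str = "2015-10-01"
    attempt_record_multiplier: float = 1.0  # <1 drops recorded attempts after switch
    background_mortality_base: float = 0.003  # annual at age 55
    true_risk_model: TrueRiskModel = field(default_factory=TrueRiskModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be > 0")
        for p in (self.psych_visit_prob, self.office_visit_prob, self.lab_measure_prob,
                  self.survey_prob, self.attempt_record_multiplier):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0,1]")
        if as_days(self.calendar_range[0]) >= as_days(self.calendar_range[1]):
            raise ConfigurationError("empty calendar range")
        if as_days(self.dob_range[0]) >= as_days(self.dob_range[1]):
            raise ConfigurationError("empty dob range")
        if as_days(self.dob_range[0]) >= as_days(self.calendar_range[1]):
            raise ConfigurationError("dob range must precede calendar range end")

    @property
    def dx_variables(self) -> list:
        return default_dx_names(self.n_dx_variables)

    @property
    def med_variables(self) -> list:
        return default_med_names(self.n_med_variables)

    @property
    def years(self) -> np.ndarray:
        y0 = pd.Timestamp(self.calendar_range[0]).year
        y1 = (pd.Timestamp(self.calendar_range[1]) - pd.Timedelta(days=1)).year
        return np.arange(y0, y1 + 1)

    def prevalences(self, rng=None) -> tuple:
        dx = self.dx_prevalence
        if dx is None:
            # named clinical variables get realistic per-visit emission rates;
            # filler diagnoses span a heavy low-prevalence tail
            named = {"suicide_ideation": 0.010, "chronic_pain": 0.030,
                     "depression": 0.025, "substance_use": 0.020,
                     "anxiety": 0.020, "ptsd": 0.015, "bipolar": 0.008,
                     "schizophrenia": 0.005, "homelessness": 0.006,
                     "tbi": 0.004, "metastatic_cancer": 0.003, "falls": 0.008,
                     "cvd": 0.030, "copd": 0.015, "diabetes": 0.030}
            fill = iter(np.geomspace(0.002, 0.02, self.n_dx_variables))
            dx = np.array([named.get(v, next(fill)) for v in self.dx_variables])
        dx = np.asarray(dx, dtype=float)
        med = self.med_prevalence
        if med is None:
            med = np.geomspace(0.003, 0.05, self.n_med_variables)
        med = np.asarray(med, dtype=float)
        if ((dx < 0) | (dx > 1)).any() or ((med < 0) | (med > 1)).any():
            raise ConfigurationError("variable prevalences must be in [0,1]")
        return dx, med

    def fingerprint(self) -> str:
        import hashlib, json

        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# population container

@dataclass
class Population:
    """Long-format tables plus the generating ground truth."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    labs: pd.DataFrame
    deaths: pd.DataFrame
    dx_variables: list
    med_variables: list
    config_fingerprint: str = ""
    truth: dict = field(default_factory=dict, repr=False)

    @property
    def variable_list(self) -> list:
        return self.dx_variables + self.med_variables + ["suicide_attempt", "overdose"]

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(path / "patients.csv", index=False)
        self.visits.to_csv(path / "visits.csv", index=False)
        self.events.to_csv(path / "events.csv", index=False)
        self.labs.to_csv(path / "labs.csv", index=False)
        self.deaths.to_csv(path / "deaths.csv", index=False)
        pd.DataFrame({"variable": self.dx_variables, "kind": "dx"}) \
            .to_csv(path / "dx_variables.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "Population":
        path = Path(path)
        dx = pd.read_csv(path / "dx_variables.csv")["variable"].tolist()
        ev = pd.read_csv(path / "events.csv")
        known = set(dx) | {"suicide_attempt", "overdose"}
        med = sorted(set(ev["variable"]) - known)
        return cls(
            patients=pd.read_csv(path / "patients.csv"),
            visits=pd.read_csv(path / "visits.csv"),
            events=ev,
            labs=pd.read_csv(path / "labs.csv"),
            deaths=pd.read_csv(path / "deaths.csv"),
            dx_variables=dx, med_variables=med,
        )


# ---------------------------------------------------------------------------
# generation

def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def generate_population(config: PopulationConfig) -> Population:
    """Generate a seeded synthetic population (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    years = config.years
    ny = len(years)
    trm = config.true_risk_model
    cal_start = as_days(config.calendar_range[0])
    cal_end = as_days(config.calendar_range[1])

    # -- demographics
    dob = rng.integers(as_days(config.dob_range[0]), as_days(config.dob_range[1]), n)
    sex = rng.choice(["M", "F"], n, p=[0.9, 0.1])
    race = rng.choice(["white", "black", "other"], n, p=[0.72, 0.18, 0.10])
    eth = rng.choice(["non_hispanic", "hispanic"], n, p=[0.93, 0.07])
    area = rng.normal(0.0, 1.0, n).round(3)
    pid = np.arange(n)

    # -- visit process: log-normal intensity, yearly Poisson counts
    lam = rng.lognormal(np.log(config.visit_rate_median), config.visit_rate_sigma, n)
    V = rng.poisson(lam[:, None], (n, ny))  # visits per patient-year

    # -- per-visit emissions of coded variables -> yearly presence + counts
    dx_prev, med_prev = config.prevalences()
    var_names = config.dx_variables + config.med_variables
    prev = np.concatenate([dx_prev, med_prev])
    nvar = len(var_names)
    A = np.zeros((n, ny, nvar), dtype=bool)
    counts = np.zeros((n, ny, nvar), dtype=np.int16)
    for v in range(nvar):
        c = rng.binomial(V, prev[v])
        counts[:, :, v] = c
        A[:, :, v] = c > 0

    # prefix sums over years for trailing-window presence of exogenous vars
    # S[:, y, v] = number of years < y with variable v present
    S = np.concatenate([np.zeros((n, 1, nvar), dtype=np.int16),
                        np.cumsum(A, axis=1, dtype=np.int16)], axis=1)
    # per-year active-variable counts, for the utilization term
    act = A.sum(axis=2, dtype=np.int32)
    Sa = np.concatenate([np.zeros((n, 1), dtype=np.int32),
                         np.cumsum(act, axis=1, dtype=np.int32)], axis=1)

    beta = {c: np.array([trm.coefficients.get(c, {}).get(v, 0.0) for v in var_names])
            for c in COMPONENTS}
    beta_att = {c: trm.coefficients.get(c, {}).get("suicide_attempt", 0.0)
                for c in COMPONENTS}
    beta_od = {c: trm.coefficients.get(c, {}).get("overdose", 0.0)
               for c in COMPONENTS}
    icpt = {c: trm.intercepts.get(c, -np.inf) for c in COMPONENTS}

    # mid-year age in decades, centered at 55 y
    year_mid_days = (years.astype(float) - 1970.0) * 365.25 + 182.0
    age_dec = (year_mid_days[None, :] - dob[:, None]) / 365.25 / 10.0
    age_term = trm.age_effect * (age_dec - 5.5)

    # -- outcome loop (annual Bernoulli hazards on the trailing 8-year state)
    WINDOW = 8
    att_A = np.zeros((n, ny), dtype=bool)   # endogenous attempt presence by year
    od_A = np.zeros((n, ny), dtype=bool)
    su_year = np.full(n, -1)
    death_year = np.full(n, 10**9)
    death_is_suicide = np.zeros(n, dtype=bool)
    att_events = np.zeros((n, ny), dtype=bool)
    od_events = np.zeros((n, ny), dtype=bool)
    truth_lp = {c: np.full((n, ny), np.nan) for c in COMPONENTS}

    for yi in range(ny):
        lo = max(0, yi - WINDOW)
        W = (S[:, yi, :] - S[:, lo, :]) > 0          # exogenous presence
        U = Sa[:, yi] - Sa[:, lo]                    # utilization cells
        w_att = att_A[:, lo:yi].any(axis=1) if yi > lo else np.zeros(n, dtype=bool)
        w_od = od_A[:, lo:yi].any(axis=1) if yi > lo else np.zeros(n, dtype=bool)
        base = trm.utilization_effect * U + age_term[:, yi]
        alive = death_year > yi
        for c in COMPONENTS:
            lp = icpt[c] + W @ beta[c] + base \
                + beta_att[c] * w_att + beta_od[c] * w_od
            truth_lp[c][:, yi] = lp
            p = _sigmoid(lp)
            draw = rng.random(n) < p
            if c == "suicide":
                hit = draw & alive & (su_year < 0)
                su_year[hit] = yi
                death_year[hit] = yi
                death_is_suicide[hit] = True
            elif c == "attempt":
                hit = draw & (death_year > yi)
                if not trm.recurrence.get("attempt", True):
                    hit &= ~att_A.any(axis=1)
                att_events[:, yi] |= hit
                att_A[:, yi] |= hit
            else:
                hit = draw & (death_year > yi)
                if not trm.recurrence.get("overdose", True):
                    hit &= ~od_A.any(axis=1)
                od_events[:, yi] |= hit
                od_A[:, yi] |= hit
        # background (non-suicide) mortality
        p_bg = config.background_mortality_base * np.exp(0.08 * (age_dec[:, yi] * 10 - 55))
        bg = (rng.random(n) < np.clip(p_bg, 0, 1)) & (death_year > yi)
        death_year[bg] = yi
        # attempts/overdoses drawn in the death year of a background death are void
        att_events[bg, yi] = False
        od_events[bg, yi] = False
        att_A[bg, yi] = False
        od_A[bg, yi] = False

    # -- materialize dates
    year_start = np.array([as_days(f"{y}-01-01") for y in years])
    year_len = np.array([as_days(f"{y + 1}-01-01") for y in years]) - year_start

    death_date = np.full(n, -1)
    has_death = death_year < 10**9
    dy = death_year[has_death]
    death_date[has_death] = year_start[dy] + rng.integers(0, year_len[dy])

    # visits: dates uniform in year, truncated at death
    vi, vy = np.nonzero(V)
    vcount = V[vi, vy]
    v_pat = np.repeat(vi, vcount)
    v_year = np.repeat(vy, vcount)
    v_date = year_start[v_year] + (rng.random(len(v_pat)) * year_len[v_year]).astype(int)
    keep = ~has_death[v_pat] | (v_date <= death_date[v_pat])
    v_pat, v_year, v_date = v_pat[keep], v_year[keep], v_date[keep]
    vtype = rng.choice(["psych", "office", "other"], len(v_pat),
                       p=[config.psych_visit_prob, config.office_visit_prob,
                          1 - config.psych_visit_prob - config.office_visit_prob])
    order = np.lexsort((v_date, v_pat))
    visits = pd.DataFrame({"patient_id": v_pat[order],
                           "date": days_to_dates(v_date[order]),
                           "visit_type": vtype[order]})

    # coded events: each emission dated at a random visit of its patient-year
    vis_sorted = np.lexsort((v_date, v_year, v_pat))
    vs_pat, vs_year, vs_date = v_pat[vis_sorted], v_year[vis_sorted], v_date[vis_sorted]
    key = vs_pat.astype(np.int64) * ny + vs_year
    uniq, start_idx, nvis = np.unique(key, return_index=True, return_counts=True)
    offset = dict(zip(uniq.tolist(), zip(start_idx.tolist(), nvis.tolist())))

    ei, ey, ev = np.nonzero(counts)
    ecount = counts[ei, ey, ev]
    e_pat = np.repeat(ei, ecount)
    e_year = np.repeat(ey, ecount)
    e_var = np.repeat(ev, ecount)
    e_key = e_pat.astype(np.int64) * ny + e_year
    e_date = np.full(len(e_pat), -1)
    # vectorized random visit pick per event
    starts = np.empty(len(e_pat), dtype=np.int64)
    sizes = np.empty(len(e_pat), dtype=np.int64)
    uk, inv = np.unique(e_key, return_inverse=True)
    uk_start = np.array([offset.get(int(k), (0, 0))[0] for k in uk], dtype=np.int64)
    uk_size = np.array([offset.get(int(k), (0, 0))[1] for k in uk], dtype=np.int64)
    starts = uk_start[inv]
    sizes = uk_size[inv]
    valid = sizes > 0  # patient-years whose visits all fell after death have none left
    pick = starts[valid] + (rng.random(valid.sum()) * sizes[valid]).astype(int)
    e_date[valid] = vs_date[pick]
    keep = valid
    e_pat, e_year, e_var, e_date = e_pat[keep], e_year[keep], e_var[keep], e_date[keep]

    switch = as_days(config.icd_switch_date)
    icd9 = e_date < switch
    var_arr = np.array(var_names, dtype=object)
    codes_icd9 = {v: f"{300 + i % 400}.{i % 10}" for i, v in enumerate(var_names)}
    codes_icd10 = {v: f"F{10 + i % 80}.{i % 10}" for i, v in enumerate(var_names)}
    e_code = np.where(icd9,
                      pd.Series(var_arr[e_var]).map(codes_icd9).to_numpy(),
                      pd.Series(var_arr[e_var]).map(codes_icd10).to_numpy())
    frames = [pd.DataFrame({"patient_id": e_pat, "date": e_date,
                            "variable": var_arr[e_var], "code": e_code,
                            "code_system": np.where(icd9, "ICD9", "ICD10")})]

    # attempt / overdose clinical events with real matching ICD codes
    for mat, name, c9, c10 in ((att_events, "suicide_attempt",
                                ATTEMPT_CODES_ICD9, ATTEMPT_CODES_ICD10),
                               (od_events, "overdose",
                                OVERDOSE_CODES_ICD9, OVERDOSE_CODES_ICD10)):
        oi, oy = np.nonzero(mat)
        if not len(oi):
            continue
        o_date = year_start[oy] + (rng.random(len(oi)) * year_len[oy]).astype(int)
        # clamp inside life span
        hd = has_death[oi]
        o_date[hd] = np.minimum(o_date[hd], death_date[oi[hd]])
        is9 = o_date < switch
        code = np.where(is9, rng.choice(c9, len(oi)), rng.choice(c10, len(oi)))
        rec = np.ones(len(oi), dtype=bool)
        if name == "suicide_attempt" and config.attempt_record_multiplier < 1.0:
            drop = (~is9) & (rng.random(len(oi)) > config.attempt_record_multiplier)
            rec = ~drop
        frames.append(pd.DataFrame({"patient_id": oi[rec], "date": o_date[rec],
                                    "variable": name, "code": code[rec],
                                    "code_system": np.where(is9[rec], "ICD9", "ICD10")}))

    events = pd.concat(frames, ignore_index=True)
    events["date"] = days_to_dates(events["date"].to_numpy())
    events = events.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    # -- deaths table
    d_pid = pid[has_death]
    d_date = death_date[has_death]
    d_sui = death_is_suicide[has_death]
    d_is9 = d_date < switch
    cause = np.empty(len(d_pid), dtype=object)
    su9 = rng.choice(SUICIDE_DEATH_CODES_ICD9, len(d_pid))
    su10 = rng.choice(SUICIDE_DEATH_CODES_ICD10, len(d_pid))
    other = rng.choice(NONSUICIDE_DEATH_CODES, len(d_pid))
    for i in range(len(d_pid)):
        if d_sui[i]:
            cause[i] = f"{su9[i]}|ICD9" if d_is9[i] else f"{su10[i]}|ICD10"
        else:
            cause[i] = f"{other[i]}|ICD10"
    deaths = pd.DataFrame({"patient_id": d_pid, "date": days_to_dates(d_date),
                           "cause_codes": cause})

    # -- labs / vitals / surveys
    labs = _generate_labs(rng, config, V, years, year_start, year_len,
                          has_death, death_date, dob, sex, A,
                          config.dx_variables)

    patients = pd.DataFrame({"patient_id": pid, "dob": days_to_dates(dob),
                             "sex": sex, "race": race, "ethnicity": eth,
                             "area_deprivation": area})

    truth = {"linear_predictors": truth_lp, "years": years,
             "coefficients": trm, "suicide_year": su_year,
             "attempt_events": att_events, "overdose_events": od_events,
             "death_year": death_year, "visit_rate": lam}
    return Population(patients=patients, visits=visits, events=events, labs=labs,
                      deaths=deaths, dx_variables=config.dx_variables,
                      med_variables=config.med_variables,
                      config_fingerprint=config.fingerprint(), truth=truth)


def _generate_labs(rng, config, V, years, year_start, year_len, has_death,
                   death_date, dob, sex, A, dx_names):
    n, ny = V.shape
    ideation_idx = dx_names.index("suicide_ideation") if "suicide_ideation" in dx_names else None
    base = {
        "systolic": rng.normal(128, 12, n),
        "diastolic": rng.normal(76, 8, n),
        "hemoglobin": rng.normal(14.5, 1.2, n) - 0.8 * (sex == "F"),
        "a1c": rng.normal(5.8, 0.7, n),
        "egfr": rng.normal(85, 18, n),
    }
    noise = {"systolic": 8, "diastolic": 6, "hemoglobin": 0.6, "a1c": 0.3, "egfr": 8}
    frames = []
    m_count = rng.binomial(V, config.lab_measure_prob)
    mi, my = np.nonzero(m_count)
    reps = m_count[mi, my]
    p_i = np.repeat(mi, reps)
    p_y = np.repeat(my, reps)
    m_date = year_start[p_y] + (rng.random(len(p_i)) * year_len[p_y]).astype(int)
    keep = ~has_death[p_i] | (m_date <= death_date[p_i])
    p_i, p_y, m_date = p_i[keep], p_y[keep], m_date[keep]
    for lab, mu in base.items():
        vals = mu[p_i] + rng.normal(0, noise[lab], len(p_i))
        if lab == "egfr":
            age = (m_date - dob[p_i]) / 365.25
            vals = vals - 0.5 * (age - 55)
        frames.append(pd.DataFrame({"patient_id": p_i, "date": m_date,
                                    "lab": lab, "value": np.round(vals, 1)}))
    # PHQ surveys tied to visit process and recent ideation
    s_count = rng.binomial(V, config.psych_visit_prob * config.survey_prob)
    si, sy = np.nonzero(s_count)
    reps = s_count[si, sy]
    s_i = np.repeat(si, reps)
    s_y = np.repeat(sy, reps)
    s_date = year_start[s_y] + (rng.random(len(s_i)) * year_len[s_y]).astype(int)
    keep = ~has_death[s_i] | (s_date <= death_date[s_i])
    s_i, s_y, s_date = s_i[keep], s_y[keep], s_date[keep]
    if len(s_i):
        recent_ideation = (A[s_i, s_y, ideation_idx] if ideation_idx is not None
                           else np.zeros(len(s_i), dtype=bool))
        phq9 = np.clip(np.round(rng.normal(4 + 8 * recent_ideation, 4)), 0, 27)
        item9 = np.clip(np.round(phq9 / 9 + rng.normal(0, 0.6, len(s_i))), 0, 3)
        phq2 = np.clip(np.round(phq9 / 4 + rng.normal(0, 1, len(s_i))), 0, 6)
        for lab, vals in (("phq9_total", phq9), ("phq9_item9", item9),
                          ("phq2_total", phq2)):
            frames.append(pd.DataFrame({"patient_id": s_i, "date": s_date,
                                        "lab": lab, "value": vals}))
    labs = pd.concat(frames, ignore_index=True)
    labs["date"] = days_to_dates(labs["date"].to_numpy())
    return labs.sort_values(["patient_id", "date", "lab"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground truth access

@dataclass
class GroundTruth:
    """Exact linear predictors used during generation, per component."""

    linear_predictors: dict  # component -> DataFrame (patient_id x year)
    coefficients: TrueRiskModel
    years: np.ndarray


def ground_truth(config: PopulationConfig, population: Population) -> GroundTruth:
    """Return the generator's own per-patient-year linear predictors.

    Raises :class:`ProvenanceError` when the population was not produced by
    ``config`` (fingerprint mismatch) or was loaded from disk without its
    ground-truth store.
    """
    if not population.truth:
        raise ProvenanceError("population carries no ground-truth store")
    if population.config_fingerprint != config.fingerprint():
        raise ProvenanceError("population/config mismatch")
    lp = {c: pd.DataFrame(population.truth["linear_predictors"][c],
                          index=population.patients["patient_id"].to_numpy(),
                          columns=population.truth["years"])
          for c in COMPONENTS}
    return GroundTruth(linear_predictors=lp,
                       coefficients=population.truth["coefficients"],
                       years=population.truth["years"])
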