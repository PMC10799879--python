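import warnings

import numpy as np
import pandas as pd
import pytest

from riskpipe.synthetic_emr import PopulationConfig, Population, generate_population
from riskpipe.cohorts import assign_dob_partitions, compute_outcomes

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_config():
    return PopulationConfig(n_patients=1500, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_parts(small_pop):
    return assign_dob_partitions(small_pop.patients, k=10)


@pytest.fixture(scope="session")
def small_outcomes(small_pop):
    return compute_outcomes(small_pop)


def make_population(patients=None, visits=None, events=None, labs=None,
                    deaths=None, dx_variables=None, med_variables=None):
    """Hand-built minimal Population for targeted cohort/encoding tests."""
    empty = {
        "patients": pd.DataFrame(columns=["patient_id", "dob", "sex", "race",
                                          "ethnicity", "area_deprivation"]),
        "visits": pd.DataFrame(columns=["patient_id", "date", "visit_type"]),
        "events": pd.DataFrame(columns=["patient_id", "date", "variable", "code",
                                        "code_system"]),
        "labs": pd.DataFrame(columns=["patient_id", "date", "lab", "value"]),
        "deaths": pd.DataFrame(columns=["patient_id", "date", "cause_codes"]),
    }
    def _df(x, key):
        if x is None:
            return empty[key]
        df = pd.DataFrame(x)
        for c in ("date", "dob"):
            if c in df.columns:
                df[c] = pd.to_datetime(df[c])
        return df
    return Population(
        patients=_df(patients, "patients"), visits=_df(visits, "visits"),
        events=_df(events, "events"), labs=_df(labs, "labs"),
        deaths=_df(deaths, "deaths"),
        dx_variables=dx_variables or ["suicide_ideation", "chronic_pain", "dx_000"],
        med_variables=med_variables or ["antidepressant_rx"],
    )
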