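"""Date helpers.

All internal arithmetic is on integer days since the Unix epoch (numpy
``datetime64[D]``); external tables use ISO-8601 strings. Intervals are
half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAY = np.timedelta64(1, "D")


def as_date(x) -> np.datetime64:
    """Coerce a scalar (str, date, Timestamp, datetime64) to datetime64[D]."""
    return np.datetime64(pd.Timestamp(x).date(), "D")


def as_days(x) -> int:
    """Integer days since epoch for a scalar date."""
    return as_date(x).astype("int64").item()


def date_col(s: pd.Series) -> np.ndarray:
    """A pandas column of dates as an int64 day-number array."""
    return pd.to_datetime(s).values.astype("datetime64[D]").astype("int64")


def days_to_dates(days: np.ndarray) -> np.ndarray:
    return np.asarray(days, dtype="int64").astype("datetime64[D]")
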