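"""Calendar-month arithmetic at day resolution.

All windows in the package are half-open [start, end). Month-granular
inputs are represented as the first day of the month.
"""

from __future__ import annotations

import calendar
import datetime as dt

import numpy as np
import pandas as pd


def month_index(d: dt.date) -> int:
    """Months elapsed since 1900-01, ignoring the day of month."""
    return (d.year - 1900) * 12 + (d.month - 1)


def date_from_month_index(mi: int, day: int = 1) -> dt.date:
    year, month = divmod(mi, 12)
    return dt.date(1900 + year, month + 1, day)


def add_months(d: dt.date, n: int) -> dt.date:
    """Shift by n calendar months, clamping the day to the target month's length."""
    mi = month_index(d) + n
    year, month = divmod(mi, 12)
    year += 1900
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def months_between(a: dt.date, b: dt.date) -> int:
    """Whole calendar months from a to b, day-of-month aware.

    (2010-01-15, 2010-02-14) -> 0; (2010-01-15, 2010-02-15) -> 1.
    Raises ValueError if a > b.
    """
    if a > b:
        raise ValueError(f"months_between requires a <= b, got {a} > {b}")
    m = month_index(b) - month_index(a)
    if b.day < a.day:
        m -= 1
    return m


# ---------------------------------------------------------------------------
# vectorized counterparts over pandas datetime Series


def month_index_series(s: pd.Series) -> np.ndarray:
    return ((s.dt.year - 1900) * 12 + (s.dt.month - 1)).to_numpy()


def months_between_series(a: pd.Series, b: pd.Series) -> np.ndarray:
    """Element-wise months_between; caller guarantees a <= b element-wise."""
    m = month_index_series(b) - month_index_series(a)
    return m - (b.dt.day.to_numpy() < a.dt.day.to_numpy())


def add_months_series(s: pd.Series, n: int) -> pd.Series:
    """Vectorized add_months with day clamping."""
    mi = month_index_series(s) + n
    year = mi // 12 + 1900
    month = mi % 12 + 1
    # days_in_month via a month-start timestamp
    firsts = pd.to_datetime({"year": year, "month": month, "day": 1})
    day = np.minimum(s.dt.day.to_numpy(), firsts.dt.days_in_month.to_numpy())
    return pd.to_datetime({"year": year, "month": month, "day": day})
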