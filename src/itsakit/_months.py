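"""Calendar-month helpers shared across modules.

All time handling is in whole calendar months via :class:`pandas.Period`
with monthly frequency; fractional month positions (used by the recovery
solver) are floats on the same axis, where integer ``k`` is the month
``origin + k``.
"""

from __future__ import annotations

import pandas as pd

MonthLike = "str | pd.Period | pd.Timestamp"


def as_month(x) -> pd.Period:
    """Coerce a 'YYYY-MM' string, Timestamp, date, or Period to a monthly Period."""
    if isinstance(x, pd.Period):
        if x.freqstr.upper().startswith("M"):
            return x
        return x.asfreq("M")
    return pd.Period(x, freq="M")


def month_range(start, end) -> pd.PeriodIndex:
    """Inclusive run of consecutive months from ``start`` to ``end``."""
    start, end = as_month(start), as_month(end)
    if end < start:
        raise ValueError(f"empty month window: {start}..{end}")
    return pd.period_range(start, end, freq="M")


def month_index(month, origin) -> int:
    """Signed number of months from ``origin`` to ``month``."""
    return (as_month(month) - as_month(origin)).n
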