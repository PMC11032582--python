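"""Monthly aggregation and enrollment-rate normalization.

The outcome modelled downstream is the monthly enrollment rate: each
month's head count expressed as a percentage of the mean monthly count
over a pre-interruption normalization window (calendar years 2017-2019
by default), computed separately within every stratum so each stratum's
window-average rate is 100 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._months import as_month, month_range
from .synthetic import DATE_COLUMN

log = logging.getLogger(__name__)

DEFAULT_NORMALIZATION_WINDOW = ("2017-01", "2019-12")


@dataclass(frozen=True)
class MonthlySeries:
    """Consecutive calendar months with counts and normalized rates (%)."""

    months: pd.PeriodIndex
    counts: np.ndarray
    rates: np.ndarray
    prepandemic_mean: float
    intervention_month: pd.Period
    stratum_label: str = "overall"
    normalization_window: tuple = DEFAULT_NORMALIZATION_WINDOW

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        n = len(self.months)
        if len(self.counts) != n or len(self.rates) != n:
            raise ValueError("months, counts and rates must have equal length")
        if n and not (np.diff(self.months.asi8) == 1).all():
            raise ValueError("months must be strictly consecutive")
        if np.any(self.counts < 0):
            raise ValueError("negative monthly count")
        if self.prepandemic_mean <= 0:
            raise ValueError("prepandemic_mean must be positive")
        expected = 100.0 * self.counts / self.prepandemic_mean
        if not np.allclose(self.rates, expected, rtol=0, atol=1e-9):
            raise ValueError("rates inconsistent with counts / prepandemic_mean")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def intervention_index(self) -> int:
        idx = (self.intervention_month - self.months[0]).n
        if not 0 <= idx < len(self):
            raise ValueError(
                f"intervention month {self.intervention_month} outside series "
                f"{self.months[0]}..{self.months[-1]}"
            )
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum_label,
                "month": self.months.astype(str),
                "count": self.counts.astype(int),
                "rate_percent": self.rates,
            }
        )


def aggregate_monthly(records: pd.DataFrame, window, where=None) -> pd.Series:
    """Count visit records per calendar month over ``window`` (zero-filled).

    ``window`` is a (start, end) month pair; ``where`` optionally selects a
    stratum, either a boolean-mask callable on the DataFrame or a mapping
    ``column -> allowed value(s)``.  Records outside the window are ignored
    (their number is logged); malformed dates raise with the row position.
    """
    months = month_range(*window)
    if records.empty:
        return pd.Series(0, index=months, dtype=int)

    df = records
    if where is not None:
        if callable(where):
            mask = np.asarray(where(df), dtype=bool)
        else:
            mask = np.ones(len(df), dtype=bool)
            for col, allowed in where.items():
                if isinstance(allowed, (str, bytes)) or not np.iterable(allowed):
                    allowed = [allowed]
                mask &= df[col].isin(list(allowed)).to_numpy()
        df = df[mask]

    try:
        dates = pd.to_datetime(df[DATE_COLUMN], errors="raise")
    except (ValueError, TypeError) as exc:
        bad = pd.to_datetime(df[DATE_COLUMN], errors="coerce")
        rows = df.index[bad.isna() & df[DATE_COLUMN].notna()].tolist()[:5]
        raise ValueError(f"unparseable visit_date in rows {rows}") from exc

    visit_months = dates.dt.to_period("M")
    inside = (visit_months >= months[0]) & (visit_months <= months[-1])
    n_out = int((~inside).sum())
    if n_out:
        log.info("aggregate_monthly: ignoring %d records outside %s..%s",
                 n_out, months[0], months[-1])
    counts = visit_months[inside].value_counts()
    return counts.reindex(months, fill_value=0).astype(int)


def normalize(
    counts: pd.Series,
    normalization_window=DEFAULT_NORMALIZATION_WINDOW,
    intervention_month="2020-03",
    stratum_label: str = "overall",
) -> MonthlySeries:
    """Convert monthly counts to enrollment rates (% of the window mean).

    The pre-interruption mean is the plain arithmetic mean of the counts
    inside ``normalization_window``; every month's rate is
    ``100 * count / mean``.  A stratum whose window mean is zero cannot be
    normalized and raises.
    """
    window = month_range(*normalization_window)
    if not isinstance(counts.index, pd.PeriodIndex):
        counts = counts.copy()
        counts.index = pd.PeriodIndex(counts.index, freq="M")
    missing = window.difference(counts.index)
    if len(missing):
        raise ValueError(
            f"counts do not cover the normalization window (missing {missing[0]}...)"
        )
    mean = float(counts.loc[window].mean())
    if mean <= 0:
        raise ValueError(
            f"stratum {stratum_label!r}: zero mean count in the normalization "
            "window; too sparse to normalize"
        )
    vals = counts.to_numpy(dtype=float)
    return MonthlySeries(
        months=pd.PeriodIndex(counts.index),
        counts=vals,
        rates=100.0 * vals / mean,
        prepandemic_mean=mean,
        intervention_month=as_month(intervention_month),
        stratum_label=stratum_label,
        normalization_window=(str(window[0]), str(window[-1])),
    )


def monthly_series(
    records: pd.DataFrame,
    window,
    normalization_window=DEFAULT_NORMALIZATION_WINDOW,
    intervention_month="2020-03",
    stratum_label: str = "overall",
    where=None,
) -> MonthlySeries:
    """aggregate_monthly + normalize in one step."""
    counts = aggregate_monthly(records, window, where=where)
    return normalize(counts, normalization_window, intervention_month, stratum_label)
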