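"""Projected enrollment-recovery dates from segmented-fit coefficients.

Two projections, both straight-line extrapolations of the fitted segments
(no uncertainty bands, no allowance for later interventions):

* **trend recovery** — the month at which the during-interruption line
  catches the extrapolated pre-interruption line, i.e. the continuous
  solution of ``b2 + b3*(t - t_c) = 0``;
* **full (100%) recovery** — the month at which the during-interruption
  line reaches a threshold rate (100% of the pre-interruption mean by
  default), i.e. ``b0 + b1*t + b2 + b3*(t - t_c) = threshold``.

Continuous crossings ``t*`` are reported in fractional months; the
calendar date is the first whole month at or after ``t*`` (ceiling).
Coefficient sets are plain inputs so published coefficient tables can be
projected directly, without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._months import as_month

DEFAULT_HORIZON = "2028-01"
DEFAULT_THRESHOLD = 100.0


@dataclass(frozen=True)
class RecoveryProjection:
    """Trend- and threshold-recovery months (or None when not reached)."""

    trend_t_star: float | None
    trend_month: pd.Period | None
    full_t_star: float | None
    full_month: pd.Period | None
    horizon: pd.Period
    threshold: float
    origin: pd.Period
    stratum_label: str = "overall"
    degenerate: bool = False

    def _fmt(self, month) -> str:
        return str(month) if month is not None else f"not_by_{self.horizon}"

    def summary(self) -> dict:
        return {
            "stratum": self.stratum_label,
            "trend_recovery": self._fmt(self.trend_month),
            "full_recovery": self._fmt(self.full_month),
            "trend_t_star": self.trend_t_star,
            "full_t_star": self.full_t_star,
            "horizon": str(self.horizon),
            "threshold": self.threshold,
        }


def _month_at_or_after(t_star: float, origin: pd.Period, horizon: pd.Period):
    """First calendar month with index >= t_star, or None past the horizon."""
    idx = math.ceil(t_star - 1e-12)
    month = origin + idx
    return month if month <= horizon else None


def trend_recovery_t(beta, intervention_index: float) -> float | None:
    """Continuous month index where the during line meets the pre trendline.

    None when the during slope never closes the gap (``b3 <= 0`` with a
    drop ``b2 < 0``); the interruption month itself when ``b2 >= 0`` (no
    drop to recover from).
    """
    _, _, b2, b3 = beta
    if b2 >= 0:
        return float(intervention_index)
    if b3 <= 0:
        return None
    return intervention_index - b2 / b3


def full_recovery_t(beta, intervention_index: float,
                    threshold: float = DEFAULT_THRESHOLD) -> float | None:
    """Continuous month index where the during line reaches ``threshold``.

    None when the line sits below the threshold and its slope
    ``b1 + b3`` is not positive.
    """
    b0, b1, b2, b3 = beta
    at_tc = b0 + b1 * intervention_index + b2
    if at_tc >= threshold:
        return float(intervention_index)
    slope = b1 + b3
    if slope <= 0:
        return None
    return intervention_index + (threshold - at_tc) / slope


def project_recovery(
    beta,
    intervention_index: int,
    origin="2017-01",
    horizon=DEFAULT_HORIZON,
    threshold: float = DEFAULT_THRESHOLD,
    stratum_label: str = "overall",
) -> RecoveryProjection:
    """Both recovery projections for one coefficient set.

    ``origin`` anchors month index 0 on the calendar (January 2017 in the
    canonical study window, making ``intervention_index`` 38 for a March
    2020 interruption).
    """
    origin = as_month(origin)
    horizon = as_month(horizon)
    b0, b1, b2, b3 = beta

    trend_t = trend_recovery_t(beta, intervention_index)
    full_t = full_recovery_t(beta, intervention_index, threshold)
    # during line flat at exactly the threshold: "recovered" only trivially
    degenerate = (
        b1 + b3 == 0 and b0 + b1 * intervention_index + b2 == threshold
    )
    return RecoveryProjection(
        trend_t_star=trend_t,
        trend_month=(
            _month_at_or_after(trend_t, origin, horizon) if trend_t is not None else None
        ),
        full_t_star=full_t,
        full_month=(
            _month_at_or_after(full_t, origin, horizon) if full_t is not None else None
        ),
        horizon=horizon,
        threshold=threshold,
        origin=origin,
        stratum_label=stratum_label,
        degenerate=degenerate,
    )


def trend_recovery(beta, intervention_index: int, origin="2017-01",
                   horizon=DEFAULT_HORIZON):
    """Calendar month of trend recovery, or None if not reached by the horizon."""
    return project_recovery(beta, intervention_index, origin, horizon).trend_month


def full_recovery(beta, intervention_index: int, threshold: float = DEFAULT_THRESHOLD,
                  origin="2017-01", horizon=DEFAULT_HORIZON):
    """Calendar month of threshold recovery, or None if not reached by the horizon."""
    return project_recovery(
        beta, intervention_index, origin, horizon, threshold
    ).full_month


def projections_frame(projections) -> pd.DataFrame:
    """Tabulate a collection of projections (CSV/JSON-ready)."""
    return pd.DataFrame([p.summary() for p in projections])
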