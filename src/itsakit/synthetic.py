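"""Synthetic baseline-visit cohort generator.

Emulates the statistical structure of a multi-center enrollment stream:
monthly expected head counts follow a segmented linear trend on the
rate scale (level drop and slope change at the interruption month),
modulated by month-of-year seasonality, with an optional forced-zero
month (April 2020 in the canonical configuration, when enrollment
halted entirely).  Counts are drawn Poisson or negative-binomial around
the expectation, and each enrollee receives attributes drawn from the
pre- or during-interruption distribution according to whether the visit
date falls before the split date (March 11, 2020 by default).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._months import as_month, month_index
from .config import GeneratorConfig, StratumSpec

ID_COLUMN = "participant_id"
DATE_COLUMN = "visit_date"
STRATUM_COLUMN = "stratum"


@dataclass(frozen=True)
class VisitRecord:
    """One baseline enrollment event: the atomic input row."""

    participant_id: str
    visit_date: pd.Timestamp
    stratum_label: str
    attributes: dict

    @classmethod
    def from_row(cls, row: pd.Series) -> "VisitRecord":
        attrs = {
            k: row[k]
            for k in row.index
            if k not in (ID_COLUMN, DATE_COLUMN, STRATUM_COLUMN)
        }
        return cls(row[ID_COLUMN], pd.Timestamp(row[DATE_COLUMN]),
                   row[STRATUM_COLUMN], attrs)


def segmented_rate(beta, t: float, intervention_index: float) -> float:
    """Segmented-trend enrollment rate (%) at month index ``t``, floored at 0.

    ``rate = b0 + b1*t + b2*D + b3*max(0, t - t_c)`` with ``D = [t >= t_c]``.
    """
    b0, b1, b2, b3 = beta
    rate = b0 + b1 * t
    if t >= intervention_index:
        rate += b2 + b3 * (t - intervention_index)
    return max(rate, 0.0)


def expected_monthly_count(config: GeneratorConfig, stratum: str, month) -> float:
    """Deterministic mean head count for one stratum-month.

    ``base_monthly_mean * rate/100 * seasonal multiplier``, truncated at 0;
    exactly 0 for the configured zero month.
    """
    spec = config.stratum(stratum)  # KeyError names the label
    month = as_month(month)
    if not (config.study_start <= month <= config.study_end):
        raise ValueError(
            f"month {month} outside study window "
            f"{config.study_start}..{config.study_end}"
        )
    if config.zero_month is not None and month == config.zero_month:
        return 0.0
    t = month_index(month, config.study_start)
    rate = segmented_rate(spec.beta, t, config.intervention_index)
    return spec.base_monthly_mean * rate / 100.0 * config.seasonality[month.month - 1]


def expected_counts(config: GeneratorConfig) -> pd.DataFrame:
    """Expected count for every stratum-month; columns are stratum labels."""
    return pd.DataFrame(
        {
            s.label: [expected_monthly_count(config, s.label, m) for m in config.months]
            for s in config.strata
        },
        index=config.months,
    )


def _draw_counts(mu: np.ndarray, noise: str, nb_dispersion, rng: np.random.Generator):
    if noise == "none":
        return np.rint(mu).astype(int)
    if noise == "poisson":
        return rng.poisson(mu)
    # gamma-Poisson mixture: var = mu + mu^2/k
    k = float(nb_dispersion)
    lam = np.where(mu > 0, rng.gamma(k, np.maximum(mu, 1e-300) / k), 0.0)
    return rng.poisson(lam)


def simulate_monthly_counts(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one realization of monthly counts per stratum (no record detail)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = expected_counts(config)
    out = mu.copy()
    for label in mu.columns:
        out[label] = _draw_counts(mu[label].to_numpy(), config.noise,
                                  config.nb_dispersion, rng)
    return out.astype(int)


def _uniform_days(month: pd.Period, n: int, rng: np.random.Generator) -> np.ndarray:
    ndays = calendar.monthrange(month.year, month.month)[1]
    return rng.integers(1, ndays + 1, size=n)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the participant-level cohort as a tidy DataFrame.

    One row per enrollee with ``participant_id``, ``visit_date``,
    ``stratum``, then one column per schema attribute.  Identical config
    and seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    counts = simulate_monthly_counts(config, rng)

    ids, dates, strata = [], [], []
    serial = 0
    for label in counts.columns:
        for month in counts.index:
            n = int(counts.at[month, label])
            if n == 0:
                continue
            days = np.sort(_uniform_days(month, n, rng))
            for d in days:
                serial += 1
                ids.append(f"P{serial:06d}")
                dates.append(pd.Timestamp(month.year, month.month, int(d)))
                strata.append(label)

    df = pd.DataFrame({ID_COLUMN: ids, DATE_COLUMN: dates, STRATUM_COLUMN: strata})
    if df.empty:
        for attr in config.attribute_schema:
            df[attr.name] = pd.Series(dtype=object)
        return df

    split = pd.Timestamp(config.split_date)
    during = (df[DATE_COLUMN] >= split).to_numpy()
    for attr in config.attribute_schema:
        col = np.empty(len(df), dtype=object)
        for period, mask in (("pre", ~during), ("during", during)):
            n = int(mask.sum())
            if n == 0:
                continue
            table = attr.table(period)
            if attr.kind == "categorical":
                levels = list(table)
                p = np.asarray([table[lv] for lv in levels], dtype=float)
                col[mask] = rng.choice(levels, size=n, p=p / p.sum())
            else:
                mean, sd = table
                col[mask] = rng.normal(mean, sd, size=n)
        df[attr.name] = col
        if attr.kind == "continuous":
            df[attr.name] = df[attr.name].astype(float)
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out[DATE_COLUMN] = pd.to_datetime(out[DATE_COLUMN]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df[DATE_COLUMN] = pd.to_datetime(df[DATE_COLUMN])
    return df
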