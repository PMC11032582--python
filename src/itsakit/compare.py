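"""Pre- versus during-interruption cohort characteristic comparisons.

Categorical attributes are tested with Pearson's chi-square on the
level-by-period contingency table (no continuity correction); continuous
attributes with the Kruskal-Wallis rank test (tie-corrected).  No
multiple-testing adjustment is applied; significance is flagged at
alpha = 0.05 per variable.  Participants are assigned to periods by
comparing the visit date to a split date (March 11, 2020 by default),
and missing values are excluded per variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DATE_COLUMN

log = logging.getLogger(__name__)

DEFAULT_SPLIT_DATE = "2020-03-11"
ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One attribute's pre/during comparison."""

    variable: str
    test: str  # "chi_square" | "kruskal_wallis"
    statistic: float
    df: int
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    n_used: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def chi_square_test(table, variable: str = "", row_labels=None,
                    col_labels=("pre", "during")) -> ComparisonResult:
    """Pearson chi-square independence test on an r x c count table.

    No continuity correction.  Errors on an all-zero row or column
    (naming the empty level); warns when any expected cell is below 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row_labels = list(row_labels) if row_labels is not None else list(range(obs.shape[0]))
    col_labels = list(col_labels)
    if len(col_labels) != obs.shape[1]:
        col_labels = list(range(obs.shape[1]))
    for axis, labels, what in ((1, row_labels, "row"), (0, col_labels, "column")):
        sums = obs.sum(axis=axis)
        if np.any(sums == 0):
            empty = labels[int(np.argmin(sums))]
            raise ValueError(f"empty {what} {empty!r} in contingency table")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected < 1):
        warnings.warn(
            f"chi-square for {variable or 'table'}: expected cell below 1; "
            "the chi-square approximation may be poor",
            stacklevel=2,
        )
    summaries = {
        str(lab): {
            str(c): int(obs[i, j]) for j, c in enumerate(col_labels)
        }
        for i, lab in enumerate(row_labels)
    }
    return ComparisonResult(
        variable=variable,
        test="chi_square",
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        group_summaries=summaries,
        n_used=int(obs.sum()),
    )


def kruskal_wallis(groups, variable: str = "",
                   group_labels=("pre", "during")) -> ComparisonResult:
    """Kruskal-Wallis rank test across two or more groups of reals.

    Uses the tie-corrected H statistic with a chi-square reference on
    k - 1 degrees of freedom.  All-tied data give H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    nonempty = [a for a in arrays if len(a)]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups")
    n_total = sum(len(a) for a in nonempty)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(nonempty)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*nonempty)
    summaries = {
        str(lab): {"n": int(len(a)),
                   "mean": float(a.mean()) if len(a) else np.nan,
                   "sd": float(a.std(ddof=1)) if len(a) > 1 else np.nan}
        for lab, a in zip(group_labels, arrays)
    }
    return ComparisonResult(
        variable=variable,
        test="kruskal_wallis",
        statistic=float(h),
        df=len(nonempty) - 1,
        p_value=float(p),
        group_summaries=summaries,
        n_used=n_total,
    )


def compare_cohorts(
    records: pd.DataFrame,
    schema: dict,
    split_date=DEFAULT_SPLIT_DATE,
    drop_levels: dict | None = None,
) -> list[ComparisonResult]:
    """Run the per-attribute test battery over a participant-level cohort.

    ``schema`` maps attribute name -> "categorical" | "continuous".
    ``drop_levels`` optionally maps attribute -> levels to exclude (the
    default keeps every observed level, including "Unknown"-style ones).
    Attributes absent from the cohort are skipped with a warning; missing
    values are excluded per attribute, with ``n_used`` reporting the rows
    actually tested.
    """
    split = pd.Timestamp(split_date)
    during = pd.to_datetime(records[DATE_COLUMN]) >= split
    period = pd.Series(np.where(during, "during", "pre"), index=records.index)
    results: list[ComparisonResult] = []
    for name, kind in schema.items():
        if name not in records.columns or records[name].notna().sum() == 0:
            log.warning("compare_cohorts: attribute %r missing or all-missing; "
                        "skipped", name)
            continue
        col = records[name]
        keep = col.notna()
        if drop_levels and name in drop_levels:
            keep &= ~col.isin(list(drop_levels[name]))
        if kind == "categorical":
            table = pd.crosstab(col[keep], period[keep])
            table = table.reindex(columns=["pre", "during"], fill_value=0)
            results.append(
                chi_square_test(
                    table.to_numpy(),
                    variable=name,
                    row_labels=[str(lv) for lv in table.index],
                )
            )
        elif kind == "continuous":
            pre_vals = col[keep & ~during].astype(float).to_numpy()
            dur_vals = col[keep & during].astype(float).to_numpy()
            results.append(kruskal_wallis([pre_vals, dur_vals], variable=name))
        else:
            raise ValueError(f"schema for {name!r}: unknown kind {kind!r}")
    return results


def comparison_frame(results) -> pd.DataFrame:
    """Flatten comparison results into a per-variable/level table."""
    rows = []
    for r in results:
        if r.test == "chi_square":
            for level, counts in r.group_summaries.items():
                pre, dur = counts.get("pre", 0), counts.get("during", 0)
                rows.append(
                    {
                        "variable": r.variable,
                        "level": level,
                        "overall": pre + dur,
                        "pre": pre,
                        "during": dur,
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "significant": r.significant,
                    }
                )
        else:
            pre = r.group_summaries.get("pre", {})
            dur = r.group_summaries.get("during", {})
            rows.append(
                {
                    "variable": r.variable,
                    "level": "mean (sd)",
                    "overall": r.n_used,
                    "pre": f"{pre.get('mean', float('nan')):.2f} ({pre.get('sd', float('nan')):.2f})",
                    "during": f"{dur.get('mean', float('nan')):.2f} ({dur.get('sd', float('nan')):.2f})",
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)
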