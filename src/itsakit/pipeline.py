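"""End-to-end orchestration: generate (or load) a cohort, aggregate and
normalize per stratum, fit the segmented model, project recovery dates,
and compare pre/during characteristics; write a consolidated report.

Strata are attribute predicates over the participant table.  The default
set mirrors the reference study's subgroup scheme: the pooled sample plus
White and Black/African American race strata (other racial groups are too
small for stable stratified fits and are available by configuring extra
strata), Hispanic and non-Hispanic ethnicity, and female and male sex.
Each stratum is normalized by its own pre-interruption mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from ._months import as_month
from .compare import comparison_frame, compare_cohorts
from .config import GeneratorConfig, default_config
from .itsa import ItsaFit, itsa_fit
from .rates import DEFAULT_NORMALIZATION_WINDOW, MonthlySeries, aggregate_monthly, normalize
from .recovery import DEFAULT_HORIZON, DEFAULT_THRESHOLD, RecoveryProjection, project_recovery, projections_frame
from .synthetic import generate_cohort, read_cohort_csv, write_cohort_csv

log = logging.getLogger(__name__)

#: a stratum needs this many nonzero-count months inside the normalization
#: window to be considered fittable
MIN_NONZERO_WINDOW_MONTHS = 24


@dataclass(frozen=True)
class StratumDef:
    """A fitted subgroup: label plus an attribute filter (None = pooled)."""

    label: str
    column: str | None = None
    values: tuple = ()

    def where(self):
        if self.column is None:
            return None
        return {self.column: list(self.values)}


DEFAULT_STRATA = (
    StratumDef("overall"),
    StratumDef("white", "race", ("White",)),
    StratumDef("black", "race", ("Black or African American",)),
    StratumDef("hispanic", "hispanic", ("Yes",)),
    StratumDef("non_hispanic", "hispanic", ("No",)),
    StratumDef("female", "sex", ("Female",)),
    StratumDef("male", "sex", ("Male",)),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one pipeline run needs."""

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    strata: tuple[StratumDef, ...] = DEFAULT_STRATA
    intervention_month: str = "2020-03"
    normalization_window: tuple = DEFAULT_NORMALIZATION_WINDOW
    lag: int = 12
    horizon: str = DEFAULT_HORIZON
    threshold: float = DEFAULT_THRESHOLD
    split_date: str = "2020-03-11"
    seed: int | None = None
    permissive: bool = False
    make_figures: bool = False

    def __post_init__(self):
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.generator is None and self.cohort_path is None:
            raise ValueError("need a generator config or a cohort path")


@dataclass
class AnalysisReport:
    """All per-stratum results of one run."""

    cohort: pd.DataFrame
    series: dict[str, MonthlySeries] = field(default_factory=dict)
    fits: dict[str, ItsaFit] = field(default_factory=dict)
    projections: dict[str, RecoveryProjection] = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)

    def rates_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.series.values()],
                         ignore_index=True)

    def fits_frame(self) -> pd.DataFrame:
        return pd.concat([f.to_frame() for f in self.fits.values()],
                         ignore_index=True)

    def projections_frame(self) -> pd.DataFrame:
        return projections_frame(self.projections.values())

    def comparisons_frame(self) -> pd.DataFrame:
        return comparison_frame(self.comparisons)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("rates", self.rates_frame()),
            ("fits", self.fits_frame()),
            ("projections", self.projections_frame()),
            ("comparisons", self.comparisons_frame()),
        ):
            if frame.empty:
                continue
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False, float_format="%.10g")
            paths[name] = path
        return paths


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full generate -> aggregate -> fit -> project -> compare run."""
    if config.cohort_path is not None:
        cohort = read_cohort_csv(config.cohort_path)
        log.info("loaded %d records from %s", len(cohort), config.cohort_path)
        gen = config.generator
    else:
        gen = config.generator
        if config.seed is not None:
            gen = gen.with_(seed=config.seed)
        cohort = generate_cohort(gen)
        log.info("generated %d records", len(cohort))

    if gen is not None:
        window = (str(gen.study_start), str(gen.study_end))
    else:
        visit_months = pd.to_datetime(cohort["visit_date"]).dt.to_period("M")
        window = (str(visit_months.min()), str(visit_months.max()))

    report = AnalysisReport(cohort=cohort)
    intervention = as_month(config.intervention_month)
    origin = as_month(window[0])
    for stratum in config.strata:
        counts = aggregate_monthly(cohort, window, where=stratum.where())
        window_counts = counts.loc[
            as_month(config.normalization_window[0]):
            as_month(config.normalization_window[1])
        ]
        n_nonzero = int((window_counts > 0).sum())
        if n_nonzero < MIN_NONZERO_WINDOW_MONTHS:
            msg = (f"only {n_nonzero} nonzero pre-interruption months "
                   f"(< {MIN_NONZERO_WINDOW_MONTHS}); too sparse to normalize")
            log.warning("stratum %r skipped: %s", stratum.label, msg)
            report.skipped[stratum.label] = msg
            if not config.permissive:
                raise ValueError(f"stratum {stratum.label!r}: {msg}")
            continue
        series = normalize(counts, config.normalization_window,
                           intervention, stratum.label)
        fit = itsa_fit(series, lag=config.lag)
        report.series[stratum.label] = series
        report.fits[stratum.label] = fit
        report.projections[stratum.label] = project_recovery(
            fit.beta,
            intervention_index=series.intervention_index,
            origin=origin,
            horizon=config.horizon,
            threshold=config.threshold,
            stratum_label=stratum.label,
        )
        log.info("stratum %r: n=%d months, DW=%.2f", stratum.label,
                 fit.n_months, fit.durbin_watson)

    schema = None
    if gen is not None and gen.attribute_schema:
        schema = {a.name: a.kind for a in gen.attribute_schema}
    else:
        meta = {"participant_id", "visit_date", "stratum"}
        schema = {
            c: ("continuous" if pd.api.types.is_numeric_dtype(cohort[c])
                else "categorical")
            for c in cohort.columns if c not in meta
        }
    if len(cohort):
        report.comparisons = compare_cohorts(cohort, schema,
                                             split_date=config.split_date)
    return report


def project_from_coefficients(
    betas: dict[str, tuple],
    intervention_index: int = 38,
    origin: str = "2017-01",
    horizon: str = DEFAULT_HORIZON,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, RecoveryProjection]:
    """Projection-only mode: run recovery projections straight from published
    or externally estimated coefficient sets (no cohort, no refit)."""
    return {
        label: project_recovery(beta, intervention_index, origin, horizon,
                                threshold, stratum_label=label)
        for label, beta in betas.items()
    }


def default_analysis_config(seed: int = 0) -> AnalysisConfig:
    """Canonical synthetic run at the study conditions."""
    return AnalysisConfig(generator=default_config(seed=seed), seed=seed)


def plot_stratum(series: MonthlySeries, fit: ItsaFit,
                 projection: RecoveryProjection | None = None, ax=None):
    """Observed rates, fitted segments, extrapolated pre-trend, recovery marks."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = np.arange(len(series))
    x = series.months.to_timestamp()
    b0, b1, b2, b3 = fit.beta
    tc = fit.intervention_index
    ax.plot(x, series.rates, "o-", ms=3, lw=0.8, alpha=0.6, label="observed rate")
    pre = t < tc
    ax.plot(x, b0 + b1 * t, "--", label="pre-trend (extrapolated)")
    ax.plot(x[~pre], b0 + b1 * t[~pre] + b2 + b3 * (t[~pre] - tc),
            "-", lw=2, label="during-trend")
    ax.axvline(x[tc], color="k", lw=0.8, alpha=0.5)
    if projection is not None:
        for month, lab in ((projection.trend_month, "trend recovery"),
                           (projection.full_month, "100% recovery")):
            if month is not None and month <= series.months[-1]:
                ax.axvline(month.to_timestamp(), ls=":", label=lab)
    ax.set_ylabel("enrollment rate (%)")
    ax.set_title(series.stratum_label)
    ax.legend(fontsize=8)
    return ax
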