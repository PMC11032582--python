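"""Generator configuration: strata, seasonality, noise law, attribute schema.

The configuration fully determines the synthetic enrollment stream; the
same seed always reproduces the same cohort.  Configurations round-trip
through plain dictionaries and YAML so pipeline runs are scriptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from . import reference
from ._months import as_month, month_range

_NOISE_LAWS = ("poisson", "negative_binomial", "none")
_PROB_TOL = 1e-9


def seasonal_multipliers(amplitude: float = 0.1, peak_month: int = 10) -> np.ndarray:
    """Cosine month-of-year multipliers ``exp(a*cos(...))`` peaking at ``peak_month``.

    The log-multipliers are a sampled cosine over the 12 months, so their
    geometric mean is exactly 1 and the seasonality does not shift the
    average level of the stream.
    """
    m = np.arange(1, 13)
    return np.exp(amplitude * np.cos(2 * np.pi * (m - peak_month) / 12.0))


@dataclass(frozen=True)
class StratumSpec:
    """True segmented-trend parameters for one generated enrollment stream.

    ``beta*`` are on the enrollment-rate scale (% of the stream's own
    pre-pandemic mean); ``base_monthly_mean`` converts rates to expected
    monthly head counts.
    """

    label: str
    base_monthly_mean: float = reference.PREPANDEMIC_MEAN_MONTHLY_ENROLLMENT
    beta0: float = 102.50
    beta1: float = -0.14
    beta2: float = -76.56
    beta3: float = 1.62

    def __post_init__(self):
        if self.base_monthly_mean <= 0:
            raise ValueError(
                f"stratum {self.label!r}: base_monthly_mean must be positive"
            )

    @property
    def beta(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)


@dataclass(frozen=True)
class AttributeSpec:
    """Distribution of one participant attribute, pre and during the interruption.

    ``kind`` is ``"categorical"`` (``pre``/``during`` are level->probability
    mappings) or ``"continuous"`` (``pre``/``during`` are (mean, sd) pairs,
    sampled as Gaussian).
    """

    name: str
    kind: str
    pre: dict | tuple
    during: dict | tuple

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            for period, table in (("pre", self.pre), ("during", self.during)):
                if not table:
                    raise ValueError(f"attribute {self.name!r}: empty {period} table")
                total = float(sum(table.values()))
                if abs(total - 1.0) > _PROB_TOL:
                    raise ValueError(
                        f"attribute {self.name!r}: {period} probabilities sum to "
                        f"{total!r}, not 1"
                    )
                if any(p < 0 for p in table.values()):
                    raise ValueError(f"attribute {self.name!r}: negative probability")
        else:
            for period, ms in (("pre", self.pre), ("during", self.during)):
                mean, sd = ms
                if sd < 0:
                    raise ValueError(f"attribute {self.name!r}: negative {period} sd")

    def table(self, period: str) -> dict | tuple:
        return self.pre if period == "pre" else self.during


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete specification of a synthetic baseline-visit stream."""

    strata: tuple[StratumSpec, ...]
    seasonality: tuple[float, ...] = tuple(np.ones(12))
    zero_month: pd.Period | str | None = "2020-04"
    noise: str = "poisson"
    nb_dispersion: float | None = None
    attribute_schema: tuple[AttributeSpec, ...] = ()
    study_start: pd.Period | str = reference.STUDY_START
    study_end: pd.Period | str = reference.STUDY_END
    intervention_month: pd.Period | str = reference.INTERVENTION_MONTH
    split_date: str = reference.PANDEMIC_SPLIT_DATE
    seed: int = 0

    def __post_init__(self):
        if not self.strata:
            raise ValueError("config needs at least one stratum")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate stratum labels: {labels}")
        if self.noise not in _NOISE_LAWS:
            raise ValueError(f"unknown noise law {self.noise!r}; pick from {_NOISE_LAWS}")
        if self.noise == "negative_binomial":
            if self.nb_dispersion is None or self.nb_dispersion <= 0:
                raise ValueError(
                    "negative_binomial noise needs nb_dispersion > 0 "
                    f"(got {self.nb_dispersion!r})"
                )
        season = np.asarray(self.seasonality, dtype=float)
        if season.shape != (12,):
            raise ValueError("seasonality must give 12 month-of-year multipliers")
        if np.any(season <= 0):
            raise ValueError("seasonality multipliers must be positive")
        # renormalize to geometric mean 1 so seasonality never shifts the level
        season = season / math.exp(np.mean(np.log(season)))
        object.__setattr__(self, "seasonality", tuple(season))
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "attribute_schema", tuple(self.attribute_schema))
        object.__setattr__(self, "study_start", as_month(self.study_start))
        object.__setattr__(self, "study_end", as_month(self.study_end))
        object.__setattr__(self, "intervention_month", as_month(self.intervention_month))
        if self.zero_month is not None:
            object.__setattr__(self, "zero_month", as_month(self.zero_month))
        if self.study_end < self.study_start:
            raise ValueError("study_end precedes study_start")
        if not (self.study_start <= self.intervention_month <= self.study_end):
            raise ValueError("intervention_month outside the study window")

    # -- convenience ------------------------------------------------------

    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.study_start, self.study_end)

    @property
    def intervention_index(self) -> int:
        return (self.intervention_month - self.study_start).n

    def stratum(self, label: str) -> StratumSpec:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(f"unknown stratum label {label!r}; "
                       f"have {[s.label for s in self.strata]}")

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "strata": [
                {
                    "label": s.label,
                    "base_monthly_mean": s.base_monthly_mean,
                    "beta0": s.beta0,
                    "beta1": s.beta1,
                    "beta2": s.beta2,
                    "beta3": s.beta3,
                }
                for s in self.strata
            ],
            "seasonality": [float(x) for x in self.seasonality],
            "zero_month": str(self.zero_month) if self.zero_month is not None else None,
            "noise": self.noise,
            "nb_dispersion": self.nb_dispersion,
            "attribute_schema": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    "pre": (
                        {k: float(v) for k, v in a.pre.items()}
                        if a.kind == "categorical"
                        else [float(x) for x in a.pre]
                    ),
                    "during": (
                        {k: float(v) for k, v in a.during.items()}
                        if a.kind == "categorical"
                        else [float(x) for x in a.during]
                    ),
                }
                for a in self.attribute_schema
            ],
            "study_start": str(self.study_start),
            "study_end": str(self.study_end),
            "intervention_month": str(self.intervention_month),
            "split_date": self.split_date,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["strata"] = tuple(StratumSpec(**s) for s in d["strata"])
        d["attribute_schema"] = tuple(
            AttributeSpec(
                name=a["name"],
                kind=a["kind"],
                pre=a["pre"] if a["kind"] == "categorical" else tuple(a["pre"]),
                during=a["during"] if a["kind"] == "categorical" else tuple(a["during"]),
            )
            for a in d.get("attribute_schema", ())
        )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_attribute_schema() -> tuple[AttributeSpec, ...]:
    """Attribute distributions matching the reference study's baseline tables."""
    specs = [
        AttributeSpec(
            name=name,
            kind="categorical",
            pre=reference.categorical_probabilities(name, "pre"),
            during=reference.categorical_probabilities(name, "during"),
        )
        for name in reference.BASELINE_CATEGORICAL_COUNTS
    ]
    specs += [
        AttributeSpec(name=name, kind="continuous", pre=pre, during=during)
        for name, (pre, during) in reference.BASELINE_CONTINUOUS_MOMENTS.items()
    ]
    return tuple(specs)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The canonical study conditions: one pooled 205/month stream, 2017-01
    through 2022-06, interruption at March 2020 with a forced-zero April 2020,
    mild cosine seasonality, Poisson counts, and attribute distributions taken
    from the reference baseline tables."""
    return GeneratorConfig(
        strata=(StratumSpec(label="overall"),),
        seasonality=tuple(seasonal_multipliers()),
        attribute_schema=default_attribute_schema(),
        seed=seed,
    )
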