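import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from itsakit import GeneratorConfig, StratumSpec, normalize

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: reference truth used throughout: the pooled segmented-fit coefficients
TRUTH = (102.50, -0.14, -76.56, 1.62)


@pytest.fixture
def flat_config():
    """Deterministic flat stream: 100% rate, 10/month, 12 months, no noise."""
    return GeneratorConfig(
        strata=(StratumSpec(label="s", base_monthly_mean=10.0,
                            beta0=100.0, beta1=0.0, beta2=0.0, beta3=0.0),),
        seasonality=tuple(np.ones(12)),
        zero_month=None,
        noise="none",
        study_start="2017-01",
        study_end="2017-12",
        intervention_month="2017-12",
        seed=0,
    )


@pytest.fixture
def truth_config():
    """Canonical 66-month stream at the reference truth, noiseless and
    season-free, so fits must recover the coefficients exactly."""
    return GeneratorConfig(
        strata=(StratumSpec(label="overall"),),
        seasonality=tuple(np.ones(12)),
        zero_month=None,
        noise="none",
        seed=0,
    )


def make_series(counts, start="2017-01", intervention="2020-03",
                norm_window=None, label="overall"):
    """Wrap raw monthly counts into a normalized MonthlySeries."""
    counts = np.asarray(counts, dtype=float)
    months = pd.period_range(start, periods=len(counts), freq="M")
    if norm_window is None:
        norm_window = (str(months[0]), str(min(months[-1], pd.Period("2019-12", "M"))))
    return normalize(pd.Series(counts, index=months), norm_window,
                     intervention, label)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def noiseless_truth_series(truth_config):
    """66-month series whose rates follow the truth exactly (up to the
    count rounding of the noise-free generator)."""
    import itsakit as ik

    counts = ik.simulate_monthly_counts(truth_config)["overall"]
    return normalize(counts, ("2017-01", "2019-12"), "2020-03")
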