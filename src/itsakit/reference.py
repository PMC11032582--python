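"""Published reference values from the motivating ADRC enrollment study.

A 2017-2022 interrupted time-series analysis of baseline enrollment across
30 US Alzheimer's Disease Research Centers (ADRCs) reported segmented
regression coefficients for the pooled sample and for strata defined by
race, Hispanic ethnicity, and sex, together with baseline characteristic
tables split at the WHO pandemic declaration (March 11, 2020).  Those
printed numbers are the worked-example inputs used throughout this
package: the coefficient sets drive recovery-date projections, and the
characteristic counts parameterize the synthetic cohort generator and the
chi-square worked examples.

Coefficients are in enrollment-rate percentage units: ``beta0`` is the
fitted rate at the study origin (January 2017), ``beta1`` the pre-pandemic
slope (%/month), ``beta2`` the immediate level change at March 2020, and
``beta3`` the slope change; the during-pandemic slope is ``beta1 + beta3``.
"""

from __future__ import annotations

STUDY_START = "2017-01"
STUDY_END = "2022-06"
INTERVENTION_MONTH = "2020-03"
PANDEMIC_SPLIT_DATE = "2020-03-11"
#: index of the interruption month when January 2017 is month 0
INTERVENTION_INDEX = 38
#: mean monthly pre-pandemic (2017-2019) enrollment across included centers
PREPANDEMIC_MEAN_MONTHLY_ENROLLMENT = 205.0
HAC_LAG = 12

#: segmented-regression estimates (beta0, beta1, beta2, beta3) per stratum
REFERENCE_FITS: dict[str, tuple[float, float, float, float]] = {
    "overall": (102.50, -0.14, -76.56, 1.62),
    "white": (105.88, -0.34, -71.15, 1.68),
    "black": (90.21, 0.64, -90.59, 0.68),
    "non_hispanic": (100.31, -0.01, -77.32, 1.33),
    "hispanic": (124.81, -1.40, -62.59, 4.42),
    "male": (99.25, 0.05, -75.25, 1.42),
    "female": (104.76, -0.27, -77.26, 1.75),
}

#: sample sizes: all participants, enrolled pre-pandemic, enrolled during
SAMPLE_SIZES = {"all": 10105, "pre": 7853, "during": 2252}

#: baseline characteristic counts by enrollment period (pre, during).
#: Categorical variables map level -> (pre_count, during_count); continuous
#: variables give (mean, sd) per period.
BASELINE_CATEGORICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {
        "Female": (4622, 1216),
        "Male": (3231, 1036),
    },
    "hispanic": {
        "Yes": (729, 247),
        "No": (7124, 2005),
    },
    "race": {
        "White": (6048, 1702),
        "Black or African American": (1097, 294),
        "American Indian or Alaska Native": (45, 20),
        "Native Hawaiian or Pacific Islander": (8, 3),
        "Asian": (271, 101),
        "Multiracial": (226, 66),
        "Unknown or ambiguous": (158, 66),
    },
    "cognitive_status": {
        "Normal cognition": (3587, 969),
        "Cognitively impaired, not MCI": (343, 57),
        "MCI": (1950, 557),
        "Dementia": (1973, 669),
    },
    "referral_source": {
        "Non-professional contact": (3045, 695),
        "Professional contact": (4062, 1316),
        "Other": (535, 194),
        "Unknown": (211, 47),
    },
}

#: continuous baseline characteristics: (pre_mean, pre_sd), (during_mean, during_sd)
BASELINE_CONTINUOUS_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((69.6, 9.9), (68.6, 9.4)),
    "education_years": ((15.8, 3.1), (16.0, 2.9)),
}


def categorical_probabilities(variable: str, period: str) -> dict[str, float]:
    """Level probabilities for ``variable`` in ``period`` ('pre' or 'during').

    Derived by normalizing the printed period counts, so the probabilities
    sum to 1 exactly up to float rounding.
    """
    idx = {"pre": 0, "during": 1}[period]
    counts = BASELINE_CATEGORICAL_COUNTS[variable]
    total = sum(v[idx] for v in counts.values())
    return {level: v[idx] / total for level, v in counts.items()}
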