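# itsakit

Interrupted time-series analysis (ITSA) of monthly clinical-research
enrollment, built around the question of how an abrupt disruption — the
COVID-19 pandemic declaration of March 2020 — changed enrollment at US
Alzheimer's Disease Research Centers (ADRCs), and when enrollment can be
expected to recover.  It is aimed at biostatisticians and study
coordinators who track recruitment streams and want segmented-regression
estimates, autocorrelation-robust inference, and projected recovery dates
from monthly visit counts.

## The model

Each month's enrollee count is normalized to an **enrollment rate**
`Y_t`, the percentage of the mean monthly pre-disruption (2017–2019)
enrollment.  The rate follows the standard single-interruption segmented
regression

```
Y_t = β0 + β1·time_t + β2·COVID_t + β3·time_since_t + ε_t
```

where `time_t` counts months from the study start (January 2017 = 0),
`COVID_t` indicates months at or after the interruption (March 2020,
index 38), and `time_since_t` is 0 through the interruption month and
then 1, 2, …  So `β0` is the fitted starting rate, `β1` the
pre-disruption slope (%/month), `β2` the immediate level change, `β3`
the slope change, and `β1 + β3` the during-disruption slope.

Coefficients are estimated by OLS; standard errors use the Newey–West
(HAC) sandwich with Bartlett weights up to lag 12, because month-of-year
patterns leave lag-12 autocorrelation in the residuals (diagnosed with
the Durbin–Watson statistic and the residual ACF).  Two recovery dates
are projected from the fitted lines: **trend recovery**, where the
during-disruption line meets the extrapolated pre-disruption line
(`t* = t_c − β2/β3`), and **100% recovery**, where it reaches 100% of
the pre-disruption mean.  Pre/during cohort characteristics are compared
with Pearson chi-square (categorical) and Kruskal–Wallis (continuous)
tests.

Because the underlying participant-level data are access-restricted, the
package ships a synthetic baseline-visit generator whose monthly
aggregates follow a configurable segmented trend with seasonality,
Poisson or negative-binomial counts, and period-dependent attribute
distributions — so the whole pipeline is testable end to end.

## Worked example

Project recovery dates straight from published coefficient sets (no data
needed — the coefficients are the input):

```python
import itsakit as ik
from itsakit.reference import REFERENCE_FITS
from itsakit.recovery import projections_frame

projs = ik.project_from_coefficients({k: REFERENCE_FITS[k]
                                      for k in ("overall", "black")})
print(projections_frame(projs.values()).to_string(index=False))
```

```
stratum trend_recovery full_recovery  trend_t_star  full_t_star horizon  threshold
overall        2024-03       2024-09     85.259259    91.635135 2028-01      100.0
  black not_by_2028-01       2025-01    171.220588    95.621212 2028-01      100.0
```

For the pooled coefficients (β2 = −76.56, β3 = 1.62) the during line
closes the 76.6-point gap at 1.62 %/month, crossing the pre-trend at
month 85.26 → March 2024, and reaches the 100% threshold at month 91.64
→ September 2024.  For the Black/African American stratum the slope
change (0.68) is too small to catch the rising pre-trend before the
January 2028 horizon, while 100% recovery still lands in January 2025.

A full synthetic run — generate a cohort at the canonical study
conditions, fit every stratum, project, and compare cohorts:

```python
report = ik.run_analysis(ik.default_analysis_config(seed=1))
print(report.fits["overall"].to_frame()[
    ["parameter", "estimate", "ci_low", "ci_high", "p_value"]].round(3))
```

```
  parameter  estimate  ci_low  ci_high  p_value
      beta0    98.111  95.098  101.124    0.000
      beta1     0.093  -0.078    0.264    0.283
      beta2   -82.685 -90.825  -74.546    0.000
      beta3     1.354   1.028    1.679    0.000
beta1+beta3     1.446   1.108    1.785    0.000
```

The generator's truth was (102.50, −0.14, −76.56, 1.62); the fitted
level change −82.7 includes the forced-zero April-2020 month and
seasonal noise, and the during-slope estimate 1.45 %/month recovers the
true 1.48.  The same pipeline is available from the shell:

```
itsakit simulate --out cohort.csv
itsakit run --seed 1 --out report/
itsakit project --beta "102.50,-0.14,-76.56,1.62"
```

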