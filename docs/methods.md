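# Methods

## Outcome and time axis

The unit of analysis is the calendar month.  Raw baseline-visit counts
are aggregated per month (zero-filled on a complete monthly grid, which
the segmented design requires) and normalized to the **monthly
enrollment rate**: 100 × count / (mean monthly count over the
normalization window, January 2017–December 2019 by default).  Each
stratum is normalized by **its own** window mean, so every stratum's
window-average rate is exactly 100 and stratum intercepts differ from
100 only through trend.  Month index 0 is the first study month
(January 2017 in the canonical window); the interruption month,
March 2020, is index 38.  For the monthly model, all of March 2020
belongs to the during period; for participant-level attribute tables the
split is the exact declaration date, March 11, 2020.

## Segmented regression and inference

The rate follows `Y_t = β0 + β1·t + β2·D_t + β3·s_t + ε_t`, with `D_t`
the during indicator and `s_t = max(0, t − 38)` (0 through the
interruption month itself, 1 the month after).  OLS gives the point
estimates; a rank check rejects designs with no months on one side of
the interruption, naming the constant columns.

Standard errors come from the Newey–West sandwich
`(XᵀX)⁻¹ S (XᵀX)⁻¹`, where `S` accumulates Bartlett-weighted
(`w_l = 1 − l/(L+1)`) lagged score cross-products up to lag `L` (12 by
default, chosen to span the month-of-year cycle).  `L = 0` reduces to
HC0.  An optional `n/(n−k)` small-sample factor is off by default.
Confidence intervals and p-values use a t reference with `n − 4` degrees
of freedom (a `use_t=False` flag switches to the normal); the
during-period slope `β1 + β3` gets its variance from the covariance
linear combination `V[1,1] + V[3,3] + 2V[1,3]`, which equals the direct
coefficient's variance under the reparameterization `[1, t−s, D, s]`.

The Durbin–Watson statistic and the residual ACF are reported as
autocorrelation diagnostics but never gate anything: the HAC lag is an
explicit user choice.  A numerically perfect fit (residuals at rounding
level) raises rather than reporting a meaningless DW and singular
covariance.

### Small-sample behaviour of the lag-12 HAC intervals

With only 66 months and a bandwidth of 12, the Bartlett HAC variance
estimator is strongly downward-biased: the calibration bundled with the
package (500 Poisson replicates at the pooled coefficient truth,
recomputed by `scripts/acceptance.py` and the test suite) finds
per-coefficient 95% CI coverage of roughly 75–85%, versus 93–97% for
HC0/OLS intervals on the same replicates, while point estimates are
essentially unbiased (β2 bias ≈ 0.01 points).  This is the documented
pathology of kernel HAC estimators when the bandwidth is comparable to
the series length, not an implementation artifact — the covariance
matches an independent double-loop computation to 1e-10 and statsmodels'
HAC to 1e-8.  Users who need calibrated intervals at this series length
should prefer a shorter lag or HC0 and model seasonality explicitly;
the lag-12 default is retained because it is the convention this
analysis follows.

## Recovery projections

Projections take a coefficient set as input (published tables work
directly; no refit needed).  Trend recovery solves `β2 + β3(t−t_c) = 0`;
100% recovery solves the during line against a threshold (default 100).
Both are straight-line extrapolations with no uncertainty bands and no
allowance for interventions after the disruption.  The continuous
crossing `t*` is reported in fractional months; the calendar date is the
first whole month at or after `t*` (ceiling).  The ceiling rule was
chosen because it reproduces the pooled reference dates (March and
September 2024) exactly from 2-decimal coefficients; since any rounding
convention can shift a date by one month when coefficients are printed
rounded, a ±1-month tolerance accompanies every reproduction check.
Edge cases: `β2 ≥ 0` recovers at the interruption month itself;
`β3 ≤ 0` with a drop never trend-recovers at any horizon; a during line
flat at exactly the threshold returns the interruption month flagged
degenerate.  Dates past the horizon (default January 2028) are reported
as "not by horizon" with `t*` still given.

## Cohort comparison

Categorical attributes: Pearson chi-square on the level × period table,
no continuity correction; an all-zero row or column errors naming the
level, and an expected cell below 1 warns.  Continuous attributes:
Kruskal–Wallis with the standard tie correction; all-tied data return
H = 0, p = 1.  Missing values are excluded per variable, "Unknown"-style
levels are kept unless explicitly dropped, and no multiple-testing
adjustment is applied (each variable is flagged at α = 0.05), matching
the exploratory character of the comparison battery.

## Synthetic cohort generator

The generator emulates the statistical structure of a pooled
multi-center enrollment stream at the canonical study conditions:
66 months (January 2017–June 2022), a pre-disruption mean of 205
enrollees/month, segmented-trend truth (102.50, −0.14, −76.56, 1.62) on
the rate scale, a forced-zero April 2020 (the month enrollment halted
entirely — the fitted during line does not itself pass through zero, so
the zero month is imposed, optionally), multiplicative month-of-year
seasonality `exp(0.1·cos)` renormalized to geometric mean 1 (which
induces the lag-12 residual autocorrelation the HAC errors are meant to
absorb), and Poisson counts (negative-binomial available for
overdispersion; the within-month count law is an assumption, as the
source analysis reports only monthly aggregates).  Visit days are
uniform within the month, since nothing downstream looks below monthly
resolution.  Attribute distributions (sex, race, ethnicity, cognitive
status, referral source, age, education) are period-dependent, with
defaults derived by normalizing the reference study's printed pre/during
baseline counts; participants are assigned the pre or during
distribution by their visit date against March 11, 2020.

The default configuration generates a single pooled stream; pipeline
strata are attribute-thinned substreams of it, which makes every
stratum's true trend shape identical to the pooled one.  That suffices
for structural and calibration testing; users who want strata with
genuinely different dynamics (e.g. a declining pre-trend in one group)
configure multiple generator strata with their own coefficients.  What
the generator does **not** emulate: site-level heterogeneity and
site-weighted means, secular attribute drift within periods,
longitudinal follow-up visits, and co-participant structure.  Passing
tests therefore validate the estimators and plumbing, not the realism of
any particular enrollment stream.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq`; rank checked with `matrix_rank`.
- The calibration simulation uses the record-free fast path (Poisson
  draws of monthly counts, no participant materialization): 500
  replicates of a 66-month fit run in under a second.
- Probability tables must sum to 1 within 1e-9 (then renormalized
  exactly); seasonality multipliers are renormalized to geometric mean 1
  on the log scale.
- The noise-free generator rounds expected counts to the nearest
  integer, so a flat integer-mean configuration reproduces its expected
  counts exactly.
- Reports are plain CSV; reruns with the same seed and configuration are
  byte-identical.
- A stratum with fewer than 24 nonzero-count months in the normalization
  window is refused (or skipped under `--permissive`) as too sparse to
  normalize stably.

## Known limitations

Point projections carry no uncertainty; the segmented model has a single
interruption and linear segments only; seasonality is handled solely
through HAC errors rather than mean-model terms; and the lag-12 HAC
intervals undercover at this series length, as quantified above.  None
of the machinery supports causal claims — there is no control series.
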