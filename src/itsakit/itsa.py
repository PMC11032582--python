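"""Segmented regression for a single-interruption time series, with
heteroskedasticity- and autocorrelation-consistent (Newey-West) inference.

Model, on the monthly enrollment-rate scale::

    Y_t = b0 + b1*time_t + b2*D_t + b3*max(0, time_t - t_c) + e_t

where ``time_t`` counts months from the study origin (0-based), ``t_c``
is the interruption month's index, ``D_t`` indicates on/after the
interruption, and ``max(0, time_t - t_c)`` is 0 through the interruption
month itself, then 1, 2, ...  ``b0`` is the fitted rate at the origin,
``b1`` the pre-interruption slope (%/month), ``b2`` the immediate level
change, ``b3`` the slope change; the during-interruption slope is
``b1 + b3``.

Coefficients come from ordinary least squares; standard errors use the
Newey-West sandwich with Bartlett weights up to a configurable lag
(12 months by default, to absorb month-of-year autocorrelation), and
confidence intervals / p-values use a t reference with n - 4 degrees of
freedom.  The Durbin-Watson statistic and the residual autocorrelation
function are reported as diagnostics but never gate the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .rates import MonthlySeries

PARAM_NAMES = ("beta0", "beta1", "beta2", "beta3")
_DURING_SLOPE_CONTRAST = np.array([0.0, 1.0, 0.0, 1.0])


class DegenerateDesignError(ValueError):
    """Design matrix is rank-deficient (e.g. no pre- or post-interruption rows)."""


# ---------------------------------------------------------------------------
# design construction


@dataclass(frozen=True)
class ItsaDesign:
    """Per-month regressors and response for the segmented model."""

    time: np.ndarray
    covid: np.ndarray
    time_since: np.ndarray
    response: np.ndarray
    intervention_index: int
    months: pd.PeriodIndex | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=int)
        if len(t) and not (np.diff(t) == 1).all():
            raise ValueError("time must increase by exactly 1 per row")
        expected_covid = (t >= self.intervention_index).astype(int)
        expected_since = np.maximum(0, t - self.intervention_index)
        if not np.array_equal(self.covid, expected_covid):
            raise ValueError("covid indicator inconsistent with intervention index")
        if not np.array_equal(self.time_since, expected_since):
            raise ValueError("time_since inconsistent with intervention index")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def is_degenerate(self) -> bool:
        """True when the series has no months on one side of the interruption."""
        return len(np.unique(self.covid)) < 2 or not np.any(self.time_since > 0)

    def matrix(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(len(self)), self.time, self.covid, self.time_since]
        ).astype(float)


def build_design(series: MonthlySeries) -> ItsaDesign:
    """Expand a monthly series into the four segmented-model regressors.

    Time index 0 is the first month of the series; the during indicator
    switches on at the interruption month, while time-since stays 0 through
    that month and becomes 1 the month after.
    """
    tc = series.intervention_index  # raises if outside the series
    t = np.arange(len(series))
    return ItsaDesign(
        time=t,
        covid=(t >= tc).astype(int),
        time_since=np.maximum(0, t - tc),
        response=np.asarray(series.rates, dtype=float),
        intervention_index=tc,
        months=series.months,
    )


# ---------------------------------------------------------------------------
# estimation primitives


def fit_ols(design: ItsaDesign) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residuals for the segmented design."""
    X = design.matrix()
    y = design.response
    if len(y) < 5:
        raise ValueError(f"need at least 5 months, got {len(y)}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        const = [
            name
            for name, col in zip(("time", "covid", "time_since"), X.T[1:])
            if np.ptp(col) == 0
        ]
        raise DegenerateDesignError(
            "design matrix is rank-deficient"
            + (f"; constant columns: {', '.join(const)}" if const else "")
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def durbin_watson(residuals) -> float:
    """Durbin-Watson statistic: sum of squared successive differences over the
    residual sum of squares; ~2 under no lag-1 autocorrelation, range [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValueError("all residuals are zero (perfect fit); DW undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def acf(residuals, max_lag: int) -> np.ndarray:
    """Sample autocorrelations r_1..r_max_lag (biased normalization)."""
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if not 0 < max_lag < n:
        raise ValueError(f"max_lag must be in 1..{n - 1}")
    d = e - e.mean()
    denom = float(np.sum(d**2))
    if denom == 0:
        raise ValueError("constant residuals; autocorrelation undefined")
    return np.array(
        [float(np.sum(d[k:] * d[:-k]) / denom) for k in range(1, max_lag + 1)]
    )


def newey_west_cov(
    X: np.ndarray, residuals, lag: int, small_sample_correction: bool = False
) -> np.ndarray:
    """Newey-West HAC sandwich covariance of the OLS coefficients.

    ``(X'X)^-1 S (X'X)^-1`` with Bartlett weights ``w_l = 1 - l/(lag+1)`` on
    the lagged score cross-products.  ``lag = 0`` reduces to the HC0
    heteroskedasticity-robust covariance.  The optional ``n/(n-k)``
    small-sample factor is off by default.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    if not 0 <= lag < n:
        raise ValueError(f"lag must be in 0..{n - 1}")
    Xe = X * e[:, None]
    S = Xe.T @ Xe
    for l in range(1, lag + 1):
        w = 1.0 - l / (lag + 1.0)
        gamma = Xe[l:].T @ Xe[:-l]
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    V = bread @ S @ bread
    if small_sample_correction:
        V *= n / (n - k)
    return (V + V.T) / 2.0


# ---------------------------------------------------------------------------
# estimator


class ITSARegressor(BaseEstimator, RegressorMixin):
    """Interrupted time-series segmented regression with Newey-West errors.

    Parameters
    ----------
    intervention_index : int, default 38
        Month index of the interruption on the fitted time axis (with a
        January-2017 origin and a March-2020 interruption this is 38).
    hac_lag : int, default 12
        Maximum lag of the Bartlett-weighted HAC covariance.
    use_t : bool, default True
        Use a t reference with ``n - 4`` degrees of freedom for intervals
        and p-values (normal reference when False).
    small_sample_correction : bool, default False
        Apply the ``n/(n-k)`` factor to the HAC covariance.
    alpha : float, default 0.05
        Two-sided miscoverage level of the reported intervals.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (4,) array — (b0, b1, b2, b3)
    resid_, fitted_ : per-month residuals and fitted values
    hac_covariance_ : (4, 4) HAC covariance
    se_, ci_low_, ci_high_, p_values_ : per-coefficient inference
    during_slope_, during_slope_se_, during_slope_ci_, during_slope_p_ :
        inference on the linear combination ``b1 + b3``
    durbin_watson_ : residual Durbin-Watson statistic
    """

    def __init__(
        self,
        intervention_index: int = 38,
        hac_lag: int = 12,
        use_t: bool = True,
        small_sample_correction: bool = False,
        alpha: float = 0.05,
    ):
        self.intervention_index = intervention_index
        self.hac_lag = hac_lag
        self.use_t = use_t
        self.small_sample_correction = small_sample_correction
        self.alpha = alpha

    # X is the (n, 1) column of integer month indices; y the rate series.
    def _design_from_X(self, X, y=None) -> ItsaDesign:
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of month indices")
            X = X[:, 0]
        t = X.astype(int)
        if not np.array_equal(t, X.astype(float)):
            raise ValueError("month indices must be integers")
        return ItsaDesign(
            time=t,
            covid=(t >= self.intervention_index).astype(int),
            time_since=np.maximum(0, t - self.intervention_index),
            response=(
                np.zeros(len(t)) if y is None else np.asarray(y, dtype=float)
            ),
            intervention_index=self.intervention_index,
        )

    def fit(self, X, y):
        design = self._design_from_X(X, y)
        beta, resid = fit_ols(design)
        scale = max(1.0, float(np.max(np.abs(design.response))))
        if np.max(np.abs(resid)) <= 1e-8 * scale:
            raise ValueError(
                "perfect fit: residuals are numerically zero, so the "
                "Durbin-Watson statistic and HAC inference are undefined"
            )
        M = design.matrix()
        V = newey_west_cov(M, resid, self.hac_lag, self.small_sample_correction)

        n = len(resid)
        se = np.sqrt(np.diag(V))
        self.df_resid_ = n - M.shape[1]
        if self.use_t:
            crit = stats.t.ppf(1 - self.alpha / 2, self.df_resid_)
            sf = lambda z: 2 * stats.t.sf(np.abs(z), self.df_resid_)
        else:
            crit = stats.norm.ppf(1 - self.alpha / 2)
            sf = lambda z: 2 * stats.norm.sf(np.abs(z))

        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        self.coef_ = beta
        self.resid_ = resid
        self.fitted_ = design.response - resid
        self.hac_covariance_ = V
        self.se_ = se
        self.ci_low_ = beta - crit * se
        self.ci_high_ = beta + crit * se
        self.p_values_ = np.asarray(sf(tvals), dtype=float)

        c = _DURING_SLOPE_CONTRAST
        ds = float(c @ beta)
        ds_var = float(c @ V @ c)
        ds_se = np.sqrt(max(ds_var, 0.0))
        self.during_slope_ = ds
        self.during_slope_se_ = ds_se
        self.during_slope_ci_ = (ds - crit * ds_se, ds + crit * ds_se)
        self.during_slope_p_ = float(sf(ds / ds_se)) if ds_se > 0 else 0.0

        self.durbin_watson_ = durbin_watson(resid)
        self.n_months_ = n
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("ITSARegressor is not fitted yet")
        return self._design_from_X(X).matrix() @ self.coef_


# ---------------------------------------------------------------------------
# result container + convenience entry point


@dataclass(frozen=True)
class ItsaFit:
    """Full inference summary of one segmented fit."""

    beta: tuple
    se: tuple
    ci_low: tuple
    ci_high: tuple
    p_value: tuple
    during_slope: float
    during_slope_se: float
    during_slope_ci: tuple
    during_slope_p: float
    durbin_watson: float
    hac_covariance: np.ndarray
    residuals: np.ndarray
    lag: int
    n_months: int
    intervention_index: int
    stratum_label: str = "overall"

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: parameter, estimate, CI, p-value, reading."""
        b0, b1, b2, b3 = self.beta
        rows = list(
            zip(
                PARAM_NAMES,
                self.beta,
                self.ci_low,
                self.ci_high,
                self.p_value,
                (
                    f"fitted enrollment rate of {b0:.2f}% at the study origin",
                    f"pre-interruption trend of {b1:.2f}%/month",
                    f"immediate level change of {b2:.2f} percentage points",
                    f"slope change of {b3:.2f}%/month at the interruption",
                ),
            )
        )
        rows.append(
            (
                "beta1+beta3",
                self.during_slope,
                self.during_slope_ci[0],
                self.during_slope_ci[1],
                self.during_slope_p,
                f"during-interruption trend of {self.during_slope:.2f}%/month",
            )
        )
        df = pd.DataFrame(
            rows,
            columns=["parameter", "estimate", "ci_low", "ci_high", "p_value",
                     "interpretation"],
        )
        df.insert(0, "stratum", self.stratum_label)
        return df


def itsa_fit(
    series: MonthlySeries,
    lag: int = 12,
    use_t: bool = True,
    small_sample_correction: bool = False,
) -> ItsaFit:
    """Fit the segmented model to a monthly series and summarize inference."""
    design = build_design(series)
    est = ITSARegressor(
        intervention_index=design.intervention_index,
        hac_lag=lag,
        use_t=use_t,
        small_sample_correction=small_sample_correction,
    ).fit(design.time[:, None], design.response)
    return ItsaFit(
        beta=tuple(est.coef_),
        se=tuple(est.se_),
        ci_low=tuple(est.ci_low_),
        ci_high=tuple(est.ci_high_),
        p_value=tuple(est.p_values_),
        during_slope=est.during_slope_,
        during_slope_se=est.during_slope_se_,
        during_slope_ci=est.during_slope_ci_,
        during_slope_p=est.during_slope_p_,
        durbin_watson=est.durbin_watson_,
        hac_covariance=est.hac_covariance_,
        residuals=est.resid_,
        lag=lag,
        n_months=est.n_months_,
        intervention_index=design.intervention_index,
        stratum_label=series.stratum_label,
    )
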