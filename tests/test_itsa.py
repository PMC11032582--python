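"""Segmented regression core: design, OLS, diagnostics, HAC inference.

Every estimation path is checked against an independent brute-force
oracle (normal equations, double-loop sandwich) and against statsmodels.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson

from itsakit import (
    ITSARegressor,
    acf,
    build_design,
    durbin_watson,
    fit_ols,
    itsa_fit,
    newey_west_cov,
)
from itsakit.itsa import DegenerateDesignError, ItsaDesign
from conftest import TRUTH, make_series


def truth_response(t, tc=38, beta=TRUTH):
    b0, b1, b2, b3 = beta
    return b0 + b1 * t + np.where(t >= tc, b2 + b3 * (t - tc), 0.0)


def design_from_rates(rates, tc=38):
    t = np.arange(len(rates))
    return ItsaDesign(
        time=t,
        covid=(t >= tc).astype(int),
        time_since=np.maximum(0, t - tc),
        response=np.asarray(rates, dtype=float),
        intervention_index=tc,
    )


def nw_bruteforce(X, e, lag):
    """Independent double-loop Newey-West sandwich."""
    n, k = X.shape
    S = np.zeros((k, k))
    for t in range(n):
        S += e[t] ** 2 * np.outer(X[t], X[t])
    for l in range(1, lag + 1):
        w = 1.0 - l / (lag + 1.0)
        for t in range(l, n):
            S += w * e[t] * e[t - l] * (
                np.outer(X[t], X[t - l]) + np.outer(X[t - l], X[t])
            )
    bread = np.linalg.inv(X.T @ X)
    return bread @ S @ bread


class TestBuildDesign:
    def test_indicator_switch_around_interruption(self, series_factory):
        series = series_factory(np.full(40, 100.0), start="2017-01")
        d = build_design(series)
        # rows 37..39 are 2020-02..2020-04
        assert d.covid[37:40].tolist() == [0, 1, 1]
        assert d.time_since[37:40].tolist() == [0, 0, 1]

    def test_intervention_index_convention(self, series_factory):
        series = series_factory(np.full(66, 100.0))
        d = build_design(series)
        assert d.intervention_index == 38
        assert int(d.covid.sum()) == 28  # Mar 2020..Jun 2022 inclusive

    def test_all_pre_design_is_degenerate(self):
        d = design_from_rates(np.full(10, 100.0), tc=20)
        assert d.is_degenerate
        assert (d.covid == 0).all() and (d.time_since == 0).all()

    def test_intervention_outside_series_errors(self, series_factory):
        series = series_factory(np.full(12, 100.0), start="2017-01",
                                intervention="2020-03",
                                norm_window=("2017-01", "2017-12"))
        with pytest.raises(ValueError, match="outside"):
            build_design(series)


class TestFitOls:
    def test_noiseless_truth_recovered_to_machine_precision(self):
        t = np.arange(66)
        d = design_from_rates(truth_response(t))
        beta, resid = fit_ols(d)
        np.testing.assert_allclose(beta, TRUTH, rtol=0, atol=1e-10)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_constant_response(self):
        d = design_from_rates(np.full(66, 100.0))
        beta, _ = fit_ols(d)
        np.testing.assert_allclose(beta, [100, 0, 0, 0], atol=1e-10)

    def test_degenerate_design_names_columns(self):
        d = design_from_rates(np.full(10, 100.0), tc=20)
        with pytest.raises(DegenerateDesignError, match="covid"):
            fit_ols(d)

    def test_too_short_series(self):
        d = design_from_rates(np.full(4, 100.0), tc=2)
        with pytest.raises(ValueError, match="at least 5"):
            fit_ols(d)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        tc = int(rng.integers(2, n - 2))
        d = design_from_rates(rng.normal(100, 10, n), tc=tc)
        beta, resid = fit_ols(d)
        X = d.matrix()
        oracle = np.linalg.solve(X.T @ X, X.T @ d.response)
        np.testing.assert_allclose(beta, oracle, rtol=0, atol=1e-8)
        np.testing.assert_allclose(resid, d.response - X @ beta, atol=1e-8)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_constant_residuals(self):
        assert durbin_watson([2.5, 2.5, 2.5, 2.5]) == pytest.approx(0.0)

    def test_all_zero_residuals_error(self):
        with pytest.raises(ValueError, match="perfect fit"):
            durbin_watson(np.zeros(10))

    def test_iid_noise_near_two(self):
        e = np.random.default_rng(1).normal(size=10_000)
        assert abs(durbin_watson(e) - 2.0) < 0.06

    def test_matches_statsmodels(self):
        e = np.random.default_rng(2).normal(size=200)
        assert durbin_watson(e) == pytest.approx(sm_durbin_watson(e), abs=1e-12)

    def test_approximates_two_times_one_minus_r1(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=5000)
        e = e[1:] + 0.5 * e[:-1]  # induce lag-1 autocorrelation
        assert durbin_watson(e) == pytest.approx(2 * (1 - acf(e, 1)[0]), abs=0.01)


class TestAcf:
    def test_twelve_month_periodicity_peaks_at_lag_12(self):
        t = np.arange(240)
        e = np.sin(2 * np.pi * t / 12)
        r = acf(e, 12)
        assert np.argmax(r) == 11  # lag 12 is maximal among lags 1..12

    def test_iid_noise_has_small_autocorrelation(self):
        e = np.random.default_rng(4).normal(size=10_000)
        assert np.all(np.abs(acf(e, 12)) < 0.05)

    def test_alternating_sequence(self):
        e = np.tile([1.0, -1.0], 50)
        assert acf(e, 1)[0] == pytest.approx(-1.0, abs=0.02)

    def test_constant_residuals_error(self):
        with pytest.raises(ValueError, match="constant"):
            acf(np.ones(10), 2)

    def test_max_lag_bounds(self):
        with pytest.raises(ValueError, match="max_lag"):
            acf(np.arange(5.0), 5)


class TestNeweyWest:
    def test_intercept_only_hand_example(self):
        X = np.ones((2, 1))
        V = newey_west_cov(X, np.array([1.0, -1.0]), lag=0)
        assert V[0, 0] == pytest.approx(0.5)
        assert np.sqrt(V[0, 0]) == pytest.approx(0.7071, abs=1e-4)

    def test_lag_zero_equals_hc0(self):
        rng = np.random.default_rng(5)
        d = design_from_rates(rng.normal(100, 10, 66))
        _, resid = fit_ols(d)
        X = d.matrix()
        V0 = newey_west_cov(X, resid, lag=0)
        Xe = X * resid[:, None]
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (Xe.T @ Xe) @ bread
        np.testing.assert_allclose(V0, hc0, atol=1e-10)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = design_from_rates(rng.normal(100, 10, 66))
        _, resid = fit_ols(d)
        X = d.matrix()
        V = newey_west_cov(X, resid, lag=12)
        np.testing.assert_allclose(V, nw_bruteforce(X, resid, 12), atol=1e-10)
        assert np.allclose(V, V.T)

    def test_matches_statsmodels_hac(self):
        rng = np.random.default_rng(6)
        d = design_from_rates(truth_response(np.arange(66)) +
                              rng.normal(0, 7, 66))
        beta, resid = fit_ols(d)
        X = d.matrix()
        fit = sm.OLS(d.response, X).fit(
            cov_type="HAC", cov_kwds={"maxlags": 12, "use_correction": False}
        )
        np.testing.assert_allclose(beta, fit.params, atol=1e-10)
        np.testing.assert_allclose(
            newey_west_cov(X, resid, 12), fit.cov_params(), atol=1e-8
        )

    def test_small_sample_correction_factor(self):
        rng = np.random.default_rng(7)
        d = design_from_rates(rng.normal(100, 10, 66))
        _, resid = fit_ols(d)
        X = d.matrix()
        plain = newey_west_cov(X, resid, 12)
        corrected = newey_west_cov(X, resid, 12, small_sample_correction=True)
        np.testing.assert_allclose(corrected, plain * 66 / 62, atol=1e-12)

    def test_level_shift_only_moves_intercept(self):
        rng = np.random.default_rng(8)
        y = truth_response(np.arange(66)) + rng.normal(0, 7, 66)
        d1, d2 = design_from_rates(y), design_from_rates(y + 50.0)
        b1, e1 = fit_ols(d1)
        b2, e2 = fit_ols(d2)
        np.testing.assert_allclose(b2 - b1, [50, 0, 0, 0], atol=1e-8)
        np.testing.assert_allclose(
            newey_west_cov(d1.matrix(), e1, 12),
            newey_west_cov(d2.matrix(), e2, 12),
            atol=1e-10,
        )

    def test_lag_bounds(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="lag"):
            newey_west_cov(X, np.ones(5), lag=5)


class TestItsaFit:
    def test_during_slope_is_exact_sum(self, series_factory):
        rng = np.random.default_rng(9)
        counts = rng.poisson(truth_response(np.arange(66)) * 2.05)
        fit = itsa_fit(make_series(counts), lag=12)
        b = fit.beta
        assert fit.during_slope == pytest.approx(b[1] + b[3], abs=1e-12)
        assert fit.during_slope_ci[0] <= fit.during_slope <= fit.during_slope_ci[1]
        for j in range(4):
            assert fit.ci_low[j] <= b[j] <= fit.ci_high[j]
        assert 0 <= fit.durbin_watson <= 4
        assert fit.lag == 12 and fit.n_months == 66

    def test_during_slope_variance_from_covariance(self, series_factory):
        rng = np.random.default_rng(10)
        counts = rng.poisson(truth_response(np.arange(66)) * 2.05)
        fit = itsa_fit(make_series(counts), lag=12)
        V = fit.hac_covariance
        var = V[1, 1] + V[3, 3] + 2 * V[1, 3]
        assert fit.during_slope_se == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_during_slope_ci_equals_reparameterized_fit(self):
        # direct-coefficient parameterization: [1, t - s, D, s] puts b1+b3
        # on the s column; its CI must match the linear-combination CI
        rng = np.random.default_rng(11)
        counts = rng.poisson(truth_response(np.arange(66)) * 2.05)
        series = make_series(counts)
        fit = itsa_fit(series, lag=12)
        d = build_design(series)
        t, s = d.time, d.time_since
        X2 = np.column_stack([np.ones(66), t - s, d.covid, s]).astype(float)
        beta2 = np.linalg.solve(X2.T @ X2, X2.T @ series.rates)
        resid2 = series.rates - X2 @ beta2
        V2 = newey_west_cov(X2, resid2, 12)
        np.testing.assert_allclose(resid2, fit.residuals, atol=1e-8)
        assert beta2[3] == pytest.approx(fit.during_slope, abs=1e-6)
        assert np.sqrt(V2[3, 3]) == pytest.approx(fit.during_slope_se, abs=1e-6)

    def test_noiseless_truth_gives_tiny_p_values(self):
        # DW is undefined on a perfect fit; add a microscopic perturbation
        y = truth_response(np.arange(66))
        y[0] += 1e-4
        fit = itsa_fit(make_series(y * 2.05), lag=12)
        assert fit.p_value[2] < 1e-12 and fit.p_value[3] < 1e-12

    def test_perfect_fit_raises_on_durbin_watson(self):
        with pytest.raises(ValueError, match="perfect fit"):
            itsa_fit(make_series(truth_response(np.arange(66)) * 2.05), lag=12)

    def test_to_frame_layout(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(truth_response(np.arange(66)) * 2.05)
        frame = itsa_fit(make_series(counts), lag=12).to_frame()
        assert frame["parameter"].tolist() == [
            "beta0", "beta1", "beta2", "beta3", "beta1+beta3"]
        assert {"estimate", "ci_low", "ci_high", "p_value",
                "interpretation"} <= set(frame.columns)


class TestEstimatorApi:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = ITSARegressor(intervention_index=38, hac_lag=12)
        assert clone(est).get_params() == est.get_params()
        rng = np.random.default_rng(13)
        t = np.arange(66)
        y = truth_response(t) + rng.normal(0, 5, 66)
        est.fit(t[:, None], y)
        np.testing.assert_allclose(est.predict(t[:, None]), est.fitted_,
                                   atol=1e-10)
        assert est.coef_.shape == (4,)
        assert est.hac_covariance_.shape == (4, 4)
        assert np.all(np.diag(est.hac_covariance_) >= 0)

    def test_estimator_matches_itsa_fit(self, series_factory):
        rng = np.random.default_rng(14)
        counts = rng.poisson(truth_response(np.arange(66)) * 2.05)
        series = make_series(counts)
        fit = itsa_fit(series, lag=12)
        est = ITSARegressor(intervention_index=38, hac_lag=12).fit(
            np.arange(66)[:, None], series.rates)
        np.testing.assert_allclose(est.coef_, fit.beta, atol=1e-12)
        np.testing.assert_allclose(est.durbin_watson_, fit.durbin_watson)
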