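import numpy as np
import pandas as pd
import pytest

from tickcast import members as mb
from tickcast.fortnights import FortnightSeries
from tickcast.members.base import ForecastDistribution
from tickcast.preprocess import LaggedPredictorSet

from conftest import FAST_ORDERS


def _lagged(frame: pd.DataFrame, train_end: int, lags=None) -> LaggedPredictorSet:
    names = list(frame.columns)
    lags = lags or {n: 1 for n in names}
    meta = pd.DataFrame(
        {"lag": [lags[n] for n in names], "correlation": 0.5,
         "mean": 0.0, "sd": 1.0, "weak": False},
        index=pd.Index(names, name="name"),
    )
    return LaggedPredictorSet(frame, meta, train_end)


class TestForecastDistribution:
    def test_interval_ordering_invariant(self, rng):
        fc = ForecastDistribution(0, rng.normal(size=(500, 8)))
        l95, u95 = fc.interval(0.95)
        l80, u80 = fc.interval(0.80)
        med = fc.median
        assert np.all(l95 <= l80) and np.all(l80 <= med)
        assert np.all(med <= u80) and np.all(u80 <= u95)

    def test_truncation_floors_paths(self):
        fc = ForecastDistribution(0, np.array([[-2.0, 1.0]]))
        assert np.all(fc.truncated().paths >= 0.0)

    def test_outcome_scale_identity_and_inverse(self, rng):
        base = ForecastDistribution(5, np.abs(rng.normal(size=(200, 6))) + 1)
        zeros = ForecastDistribution(5, np.zeros((200, 6)))
        same = mb.to_outcome_scale(base, zeros)
        assert np.allclose(same.paths, base.paths)
        # keep sums positive so the zero-floor never engages
        seasonal = ForecastDistribution(5, rng.uniform(-0.5, 0.5, size=(200, 6)))
        added = mb.to_outcome_scale(base, seasonal)
        # adding then subtracting the same seasonal paths recovers the original
        recovered = ForecastDistribution(5, added.paths - seasonal.paths)
        assert np.allclose(np.quantile(recovered.paths, 0.5, axis=0), base.median)

    def test_outcome_scale_truncates(self):
        sa = ForecastDistribution(0, np.array([[-2.0]]))
        seas = ForecastDistribution(0, np.array([[1.0]]))
        assert mb.to_outcome_scale(sa, seas).paths[0, 0] == 0.0

    def test_outcome_scale_horizon_mismatch(self):
        a = ForecastDistribution(0, np.zeros((10, 3)))
        b = ForecastDistribution(0, np.zeros((10, 4)))
        with pytest.raises(ValueError):
            mb.to_outcome_scale(a, b)

    def test_log1p_back_transform_zero_maps_to_zero(self):
        fc = ForecastDistribution(0, np.array([[0.0, np.log(3.0)]]))
        out = mb.back_transform_counts(fc)
        assert out.paths[0, 0] == 0.0
        assert out.paths[0, 1] == pytest.approx(2.0)


def _simulate_arma11(n, beta, rng, n_noise=3):
    X = rng.normal(size=(n, 1 + n_noise))
    e = np.empty(n + 1)
    e[0] = rng.normal()
    y = np.empty(n)
    prev_y = 0.0
    for t in range(n):
        e[t + 1] = rng.normal()
        resid_prev = prev_y  # AR on the regression-adjusted scale
        y[t] = 0.6 * prev_y + e[t + 1] + 0.3 * e[t]
        prev_y = y[t]
    y = y + X[:, 0] * beta
    return y, X


class TestArimaMember:
    def test_recovers_injected_regressor(self, rng):
        n = 500
        y, X = _simulate_arma11(n, beta=1.0, rng=rng)
        frame = pd.DataFrame(X, columns=["true_x"] + [f"noise{i}" for i in range(3)])
        target = FortnightSeries(y, 2000)
        fit = mb.fit_arima_seasadj(target, _lagged(frame, n), max_predictors=2,
                                   order_grid=((1, 0, 1), (1, 0, 0), (0, 0, 1)))
        assert "true_x" in fit.selected
        names = list(fit.results.params.index) if hasattr(fit.results.params, "index") \
            else list(fit.results.param_names)
        i = names.index("true_x") if "true_x" in names else 1
        beta_hat = np.asarray(fit.results.params)[i]
        se = np.asarray(fit.results.bse)[i]
        assert abs(beta_hat - 1.0) < 2 * se

    def test_zero_candidates_gives_plain_arima(self, rng):
        y = rng.normal(size=200)
        fit = mb.fit_arima_seasadj(FortnightSeries(y, 2000), None,
                                   order_grid=FAST_ORDERS)
        assert fit.selected == ()
        assert np.isfinite(fit.fit_metadata["bic"])

    def test_duplicated_regressor_never_lowers_bic(self, rng):
        n = 300
        y, X = _simulate_arma11(n, beta=1.0, rng=rng, n_noise=0)
        frame1 = pd.DataFrame({"x": X[:, 0]})
        frame2 = pd.DataFrame({"x": X[:, 0], "x_copy": X[:, 0] + 1e-9 * rng.normal(size=n)})
        target = FortnightSeries(y, 2000)
        grid = ((1, 0, 1),)
        fit1 = mb.fit_arima_seasadj(target, _lagged(frame1, n), max_predictors=1, order_grid=grid)
        fit2 = mb.fit_arima_seasadj(target, _lagged(frame2, n), max_predictors=2, order_grid=grid)
        assert fit2.fit_metadata["bic"] >= fit1.fit_metadata["bic"] - 1e-6 or \
            set(fit2.selected) == {"x"}

    def test_nonfinite_rejected(self):
        y = np.ones(100)
        y[3] = np.nan
        with pytest.raises(ValueError):
            mb.fit_arima_seasadj(FortnightSeries(y, 2000), None, order_grid=FAST_ORDERS)

    def test_simulated_interval_matches_closed_form(self, rng):
        # Gaussian ARMA: the 95% band from simulated paths should agree with
        # the analytic forecast interval within Monte-Carlo error
        y, _ = _simulate_arma11(400, beta=0.0, rng=rng, n_noise=0)
        target = FortnightSeries(y, 2000)
        fit = mb.fit_arima_seasadj(target, None, order_grid=((1, 0, 1),))
        fc = mb.forecast(fit, 8, n_paths=4000, seed=1)
        analytic = fit.results.get_forecast(8)
        ci = analytic.conf_int(alpha=0.05)
        lo, up = fc.interval(0.95)
        width = up - lo
        assert np.allclose(lo, ci[:, 0], atol=0.12 * width)
        assert np.allclose(up, ci[:, 1], atol=0.12 * width)

    def test_forecast_determinism(self, rng):
        y, _ = _simulate_arma11(150, beta=0.0, rng=rng, n_noise=0)
        fit = mb.fit_arima_seasadj(FortnightSeries(y, 2000), None, order_grid=((1, 0, 0),))
        a = mb.forecast(fit, 6, n_paths=50, seed=7)
        b = mb.forecast(fit, 6, n_paths=50, seed=7)
        assert np.array_equal(a.paths, b.paths)


@pytest.fixture(scope="module")
def homoskedastic_fit():
    rng = np.random.default_rng(2)
    n = 250
    X = rng.normal(size=(n, 2))
    y = 0.5 + 0.0 * X[:, 0] + rng.normal(0.0, 1.0, size=n)
    frame = pd.DataFrame(X, columns=["null_a", "null_b"])
    target = FortnightSeries(y, 2000)
    return mb.fit_garch_seasadj(target, _lagged(frame, n),
                                n_steps=900, n_burn=300, seed=3)


class TestGarchMember:
    def test_volatility_posteriors_near_zero_when_homoskedastic(self, homoskedastic_fit):
        fit = homoskedastic_fit
        assert abs(fit.params["a1"]) < 0.25
        assert abs(fit.params["a2"]) < 0.25

    def test_null_predictor_ci_covers_zero_in_most_replicates(self):
        # scaled-down coverage simulation: the 95% credible interval of a
        # no-effect coefficient should cover zero in most replicates
        covered = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n = 150
            X = rng.normal(size=(n, 1))
            y = 0.5 + rng.normal(0.0, 1.0, size=n)
            frame = pd.DataFrame(X, columns=["null_a"])
            fit = mb.fit_garch_seasadj(FortnightSeries(y, 2000), _lagged(frame, n),
                                       n_steps=700, n_burn=250, seed=rep)
            lo, hi = fit.fit_metadata["ci95"]["null_a"]
            covered += (lo < 0.0 < hi)
        assert covered >= 4

    def test_long_horizon_mean_reverts_to_series_mean(self, homoskedastic_fit):
        fit = homoskedastic_fit
        zeros = np.zeros((24, 2))
        paths = fit.simulate_paths(24, 3000, np.random.default_rng(0), zeros)
        assert paths[:, -1].mean() == pytest.approx(0.5, abs=0.15)

    def test_retains_1000_draws_and_reports_rhat(self, homoskedastic_fit):
        assert homoskedastic_fit.fit_metadata["n_draws"] == 1000
        assert np.isfinite(homoskedastic_fit.rhat_max)


@pytest.fixture(scope="module")
def nb_fit():
    # NB counts with known seasonal/trend structure, phi = 2, one real and
    # one null predictor
    rng = np.random.default_rng(4)
    n = 264
    f = np.tile(np.arange(1, 25), n // 24)
    season = 0.9 * np.sin(2 * np.pi * (f - 6) / 24)
    trend = 0.4 * np.sin(np.arange(n) / n * np.pi)
    x_real = rng.normal(size=n)
    x_null = rng.normal(size=n)
    mu = np.exp(np.log(3.0) + season + trend + 0.5 * x_real)
    phi = 2.0
    y = rng.negative_binomial(phi, phi / (phi + mu))
    counts = FortnightSeries(y, 2000)
    frame = pd.DataFrame({"x_real": x_real, "x_null": x_null})
    fit = mb.fit_gam_raw(counts, _lagged(frame, n))
    return fit, phi


class TestGamMember:
    def test_phi_recovered_within_half(self, nb_fit):
        fit, phi = nb_fit
        assert abs(fit.phi - phi) / phi < 0.5

    def test_null_predictor_shrunk_to_zero_edf(self, rng):
        # at a comfortable sample size, the shrinkage ridge collapses a
        # no-effect predictor's smooth while keeping the real one
        n = 480
        f = np.tile(np.arange(1, 25), n // 24)
        season = 0.9 * np.sin(2 * np.pi * (f - 6) / 24)
        x_real = rng.normal(size=n)
        x_null = rng.normal(size=n)
        mu = np.exp(np.log(3.0) + season + 0.5 * x_real)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu)).astype(float)
        frame = pd.DataFrame({"x_real": x_real, "x_null": x_null})
        fit = mb.fit_gam_raw(FortnightSeries(y, 2000), _lagged(frame, n))
        null_term = next(k for k in fit.edf if "x_null" in k)
        real_term = next(k for k in fit.edf if "x_real" in k)
        assert fit.edf[null_term] < 0.6
        assert fit.edf[real_term] > 1.0

    def test_cyclic_seasonal_effect_is_continuous_at_the_year_boundary(self, nb_fit):
        fit, _ = nb_fit
        import patsy

        lo = {"t_year": [5.0], "fn": [1.0], "x_real": [0.0], "x_null": [0.0]}
        hi = {"t_year": [5.0], "fn": [24.999999], "x_real": [0.0], "x_null": [0.0]}
        (Xlo,) = patsy.build_design_matrices([fit.design_info], lo)
        (Xhi,) = patsy.build_design_matrices([fit.design_info], hi)
        eta_lo = (np.asarray(Xlo) @ fit.beta).item()
        eta_hi = (np.asarray(Xhi) @ fit.beta).item()
        # fortnight 25 is identified with fortnight 1: the fitted seasonal
        # effect wraps continuously across the year boundary
        assert abs(eta_hi - eta_lo) < 0.2

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            mb.fit_gam_raw(FortnightSeries(np.zeros(96), 2000), None)

    def test_forecast_paths_are_nonnegative_integers(self, nb_fit):
        fit, _ = nb_fit
        fc = mb.forecast(fit, 6, n_paths=200, seed=5)
        assert np.all(fc.paths >= 0)
        assert np.allclose(fc.paths, np.round(fc.paths))


class TestProphetMember:
    def test_deviance_ranking_prefers_shifted_copy_of_target(self, rng):
        n = 240
        y = np.clip(rng.poisson(3.0, size=n).astype(float), 0, None)
        counts = FortnightSeries(y, 2000)
        signal = np.log1p(y) + 0.05 * rng.normal(size=n)
        frame = pd.DataFrame({
            "copycat": signal,
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        })
        fit = mb.fit_prophet_raw(counts, _lagged(frame, n), n_predictors=1)
        assert fit.fit_metadata["selected"] == ["copycat"]

    def test_zero_noise_linear_trend_has_tiny_changepoints(self):
        n = 240
        y = np.expm1(0.002 * np.arange(n) + 0.5)  # exactly linear on log1p scale
        counts = FortnightSeries(y, 2000)
        fit = mb.fit_prophet_raw(counts, None)
        assert fit.fit_metadata["max_abs_delta"] < 1e-2

    def test_warns_when_fewer_candidates_than_requested(self, rng):
        n = 120
        counts = FortnightSeries(rng.poisson(2.0, size=n).astype(float), 2000)
        frame = pd.DataFrame({"only": rng.normal(size=n)})
        with pytest.warns(UserWarning):
            mb.fit_prophet_raw(counts, _lagged(frame, n), n_predictors=3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mb.fit_prophet_raw(FortnightSeries(np.array([-1.0] * 120), 2000), None)


class TestEtsMember:
    def test_deterministic_seasonal_pattern_reproduced(self):
        pattern = np.array([1.0, 2.0, 5.0, 9.0, 6.0, 3.0] * 4)
        y = np.tile(pattern, 5)
        series = FortnightSeries(y, 2000)
        fit = mb.fit_ets(series, "seasonal_component")
        fc = mb.forecast(fit, 24, n_paths=300, seed=1)
        assert np.allclose(fc.median, pattern, atol=0.05)
        lo, up = fc.interval(0.95)
        assert np.all(up - lo < 0.5)

    def test_constant_series_flat_forecast(self):
        series = FortnightSeries(np.full(96, 4.0), 2000)
        fit = mb.fit_ets(series, "seasonal_component")
        fc = mb.forecast(fit, 6, n_paths=200, seed=2)
        assert np.allclose(fc.median, 4.0, atol=0.05)

    def test_benchmark_back_transform_contract(self, study):
        fit = mb.fit_ets(study["counts"], "log1p_count", train_end=225)
        fc = mb.back_transform_counts(mb.forecast(fit, 6, n_paths=300, seed=3))
        assert np.all(fc.paths >= 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mb.fit_ets(FortnightSeries(np.ones(60), 2000), "log1p_count")

    def test_unknown_scale_rejected(self, study):
        with pytest.raises(ValueError):
            mb.fit_ets(study["counts"], "sqrt_count")


class TestCalibration:
    def test_nominal_95_interval_covers_at_scale(self):
        # data generated from the fitted model family: empirical coverage of
        # the nominal 95% band stays near nominal (scaled-down check)
        rng = np.random.default_rng(9)
        hits = total = 0
        for _ in range(8):
            y, _ = _simulate_arma11(220, beta=0.0, rng=rng, n_noise=0)
            fit = mb.fit_arima_seasadj(FortnightSeries(y[:200], 2000), None,
                                       order_grid=((1, 0, 1),), train_end=200)
            fc = mb.forecast(fit, 12, n_paths=800, seed=int(rng.integers(2**31)))
            lo, up = fc.interval(0.95)
            future = y[200:212]
            hits += np.sum((future >= lo) & (future <= up))
            total += 12
        assert hits / total >= 0.85
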