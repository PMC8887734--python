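import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tickcast import preprocess as pp
from tickcast.fortnights import FORTNIGHTS_PER_YEAR, FortnightSeries
from tickcast.simulate import SimulationConfig, simulate_cases, simulate_covariates


def _records(rows):
    return pd.DataFrame(rows, columns=["admission_date", "clinic_id", "species", "record_class"])


class TestDedup:
    def test_window_definition(self):
        recs = _records([
            (dt.date(2010, 1, 1), "c1", "dog", "confirmed"),
            (dt.date(2010, 1, 4), "c1", "dog", "confirmed"),  # 3 days later: duplicate
            (dt.date(2010, 1, 24), "c1", "dog", "confirmed"),  # 20 days after retained: kept
        ])
        out = pp.dedupe_cases(recs, 14)
        assert len(out) == 2

    def test_streams_are_independent(self):
        recs = _records([
            (dt.date(2010, 1, 1), "c1", "dog", "confirmed"),
            (dt.date(2010, 1, 2), "c2", "dog", "confirmed"),
            (dt.date(2010, 1, 3), "c1", "cat", "confirmed"),
        ])
        assert len(pp.dedupe_cases(recs, 14)) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        base = dt.date(2010, 1, 1)
        recs = _records([
            (base + dt.timedelta(days=int(d)), f"c{rng.integers(1, 4)}", "dog", "confirmed")
            for d in rng.integers(0, 400, size=80)
        ])
        once = pp.dedupe_cases(recs, 14)
        twice = pp.dedupe_cases(once, 14)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            pp.dedupe_cases(_records([]), -1)

    def test_removes_exactly_the_injected_duplicates_when_streams_are_sparse(self):
        # base admissions spaced beyond the window, plus known injected
        # re-recordings: dedup removes exactly those
        base = [
            (dt.date(2010, 1, 1) + dt.timedelta(days=30 * i), "c1", "dog", "confirmed")
            for i in range(10)
        ]
        dups = [(d + dt.timedelta(days=5), c, s, r) for d, c, s, r in base[::2]]
        out = pp.dedupe_cases(_records(base + dups), 14)
        assert len(out) == len(base)

    def test_generator_bookkeeping_on_sparse_config(self):
        # one clinic, low baseline: true admissions rarely collide, so the
        # output size tracks input minus the generator's injected duplicates
        cfg = SimulationConfig(n_years=4, baseline=0.25, n_clinics=1,
                               false_positive_rate=0.0, duplicate_rate=0.4,
                               covariate_effects={}, rng_seed=21)
        cov = simulate_covariates(cfg)
        res = simulate_cases(cfg, cov)
        out = pp.dedupe_cases(res.records, cfg.duplicate_window_days)
        removed = len(res.records) - len(out)
        assert removed >= res.n_duplicates  # every injected duplicate goes
        assert removed <= res.n_duplicates + 0.5 * (len(res.records) - res.n_duplicates)


class TestBinning:
    def test_boundary_convention(self):
        recs = _records([
            (dt.date(2010, 1, 15), "c1", "dog", "confirmed"),
            (dt.date(2010, 1, 16), "c1", "dog", "confirmed"),
        ])
        series = pp.bin_fortnights(recs, 2010, 2010)
        assert series.values[0] == 1  # fortnight 1
        assert series.values[1] == 1  # fortnight 2

    def test_eleven_years_is_264_bins_and_conserves_count(self, study):
        counts = study["counts"]
        assert len(counts) == 264
        deduped = pp.dedupe_cases(study["result"].records, 14)
        assert counts.values.sum() == len(deduped)

    def test_empty_records_zero_series(self):
        series = pp.bin_fortnights(_records([]), 2010, 2012)
        assert len(series) == 3 * FORTNIGHTS_PER_YEAR
        assert np.all(series.values == 0)

    def test_out_of_range_date_rejected(self):
        recs = _records([(dt.date(2013, 2, 1), "c1", "dog", "confirmed")])
        with pytest.raises(ValueError):
            pp.bin_fortnights(recs, 2010, 2012)


class TestSTL:
    def test_constant_series(self):
        series = FortnightSeries(np.full(96, 7.0), 2010)
        d = pp.stl_decompose(series)
        assert np.allclose(d.trend.values, 7.0, atol=1e-6)
        assert np.allclose(d.seasonal.values, 0.0, atol=1e-6)
        assert np.allclose(d.remainder.values, 0.0, atol=1e-6)

    def test_pure_sinusoid_lands_in_seasonal(self):
        t = np.arange(240)
        x = np.sin(2 * np.pi * t / 24)
        d = pp.stl_decompose(FortnightSeries(x, 2000))
        assert np.var(d.seasonal.values) > 0.9 * np.var(x)
        assert np.max(np.abs(d.remainder.values)) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pp.stl_decompose(FortnightSeries(np.ones(47), 2010))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_additivity_always(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 2.0, size=120)
        series = FortnightSeries(x, 2010)
        d = pp.stl_decompose(series)
        assert np.max(np.abs(d.reconstruct() - x)) < 1e-8


class TestSeasonalAdjustment:
    def test_conservation_and_variance_reduction(self, study):
        d = study["decomp"]
        adj = study["seasadj"]
        assert np.allclose(adj.values + d.seasonal.values, study["counts"].values)
        assert adj.values.var() < study["counts"].values.var()

    def test_zero_seasonal_is_identity(self):
        x = np.random.default_rng(1).normal(size=96)
        series = FortnightSeries(x, 2010)
        zero = series.with_values(np.zeros_like(x))
        d = pp.STLDecomposition(zero, series, zero)
        assert np.allclose(pp.seasonally_adjust(d).values, x)


class TestADF:
    def test_white_noise_stationary(self):
        x = np.random.default_rng(3).normal(size=500)
        stat, p = pp.adf_test(FortnightSeries(x[:480], 2000))
        assert p < 0.05

    def test_random_walk_nonstationary(self):
        x = np.cumsum(np.random.default_rng(4).normal(size=480))
        stat, p = pp.adf_test(FortnightSeries(x, 2000))
        assert p > 0.05

    def test_location_invariance(self):
        x = np.random.default_rng(5).normal(size=240)
        s1, _ = pp.adf_test(FortnightSeries(x, 2000))
        s2, _ = pp.adf_test(FortnightSeries(x + 100.0, 2000))
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.adf_test(FortnightSeries(np.ones(100), 2000))
        with pytest.raises(ValueError):
            pp.adf_test(FortnightSeries(np.arange(10.0), 2000))


class TestMoistVegetation:
    def test_printed_arithmetic(self):
        out = pp.moist_vegetation([10.0], [2.0], [0.3], [0.2])
        assert out[0] == pytest.approx(-10.0)

    @pytest.mark.parametrize("rain,et,shrub,forest", [(0, 5, 0.3, 0.2), (10, 5, 0.0, 0.0)])
    def test_zero_factors(self, rain, et, shrub, forest):
        assert pp.moist_vegetation([rain], [et], [shrub], [forest])[0] == 0.0

    def test_intended_form_is_positive_in_rainfall(self):
        lo = pp.moist_vegetation([5.0], [2.0], [0.3], [0.2], intended_form=True)[0]
        hi = pp.moist_vegetation([10.0], [2.0], [0.3], [0.2], intended_form=True)[0]
        assert 0 < lo < hi

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            pp.moist_vegetation([1.0, 2.0], [1.0], [0.1], [0.1])


class TestQuarterlyAnomaly:
    def _grid(self, n_years):
        fns = np.tile(np.arange(1, 25), n_years)
        yrs = np.repeat(np.arange(2000, 2000 + n_years), 24)
        return fns, yrs

    def test_yearly_repetition_gives_zero(self):
        fns, yrs = self._grid(4)
        vals = np.tile(np.arange(24, dtype=float), 4)
        assert np.allclose(pp.quarterly_anomaly(vals, fns, yrs), 0.0)

    def test_centering_within_window(self):
        rng = np.random.default_rng(6)
        fns, yrs = self._grid(5)
        vals = rng.normal(size=len(fns))
        anom = pp.quarterly_anomaly(vals, fns, yrs)
        from tickcast.fortnights import quarter_of_fortnight
        quarters = np.array([quarter_of_fortnight(int(f)) for f in fns])
        for q in range(4):
            assert anom[quarters == q].mean() == pytest.approx(0.0, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        fns, yrs = self._grid(3)
        a, b = rng.normal(size=len(fns)), rng.normal(size=len(fns))
        lhs = pp.quarterly_anomaly(a + b, fns, yrs)
        rhs = pp.quarterly_anomaly(a, fns, yrs) + pp.quarterly_anomaly(b, fns, yrs)
        assert np.allclose(lhs, rhs)

    def test_single_year_shift_algebra(self):
        n_years = 5
        fns, yrs = self._grid(n_years)
        vals = np.zeros(len(fns))
        base = pp.quarterly_anomaly(vals, fns, yrs)
        shifted = vals.copy()
        year0_q1 = slice(0, 6)  # Jan-Mar of the first year
        shifted[year0_q1] += 2.0
        anom = pp.quarterly_anomaly(shifted, fns, yrs)
        assert np.allclose(anom[year0_q1] - base[year0_q1], 2.0 * (1 - 1 / n_years))

    def test_short_climatology_rejected(self):
        fns, yrs = self._grid(1)
        with pytest.raises(ValueError):
            pp.quarterly_anomaly(np.zeros(24), fns, yrs)


class TestCollinearityPruning:
    def test_duplicated_covariate_keeps_one(self, rng):
        x = rng.normal(size=200)
        frame = pd.DataFrame({"max_temperature": x, "min_temperature": x})
        assert pp.prune_collinear(frame) == ["max_temperature"]

    def test_independent_covariates_all_retained(self, rng):
        frame = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        assert pp.prune_collinear(frame) == list("abcd")

    def test_threshold_zero_collapses_cluster(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        assert len(pp.prune_collinear(frame, threshold=0.0)) == 1

    def test_reproduces_study_removals(self, study):
        # raw minimum temperature and raw NDVI fall to their higher-priority
        # collinear partners under the default priority list
        retained = study["retained"]
        assert "min_temperature" not in retained
        assert "ndvi" not in retained
        assert "ndvi_anomaly" in retained


class TestLagSelection:
    def test_recovers_constructed_shift(self, rng):
        n, lead = 240, 6
        target_vals = rng.normal(size=n)
        target = FortnightSeries(target_vals, 2000)
        cov = np.empty(lead + n)
        cov[: lead - 3] = rng.normal(size=lead - 3)
        cov[lead - 3 : lead - 3 + n] = target_vals + 0.1 * rng.normal(size=n)
        cov[lead - 3 + n :] = rng.normal(size=3)
        frame = pd.DataFrame({"x": cov})
        out = pp.select_lags(frame, target, max_lag=6, lead=lead)
        assert int(out.meta.loc["x", "lag"]) == 3
        assert not bool(out.meta.loc["x", "weak"])

    def test_unit_variance_on_training_window(self, study):
        lagged = study["lagged"]
        train = lagged.frame.iloc[: lagged.train_end]
        assert np.allclose(train.std(ddof=1), 1.0)

    def test_white_noise_flagged_weak(self, rng):
        target = FortnightSeries(rng.normal(size=300), 2000)
        frame = pd.DataFrame({"noise": rng.normal(size=306)})
        out = pp.select_lags(frame, target, max_lag=6, lead=6, weak_threshold=0.15)
        assert 1 <= int(out.meta.loc["noise", "lag"]) <= 6
        assert bool(out.meta.loc["noise", "weak"])

    def test_zero_variance_rejected(self, rng):
        target = FortnightSeries(rng.normal(size=100), 2000)
        with pytest.raises(ValueError):
            pp.select_lags(pd.DataFrame({"flat": np.ones(106)}), target, lead=6)

    def test_future_rows_respect_lag_availability(self, study):
        lagged = study["lagged"]
        origin = lagged.train_end - 1
        rows = lagged.future_rows(origin, 12, persistence=True)
        assert rows.shape == (12, len(lagged.names))
        assert np.all(np.isfinite(rows))
        if lagged.min_lag < 12:
            with pytest.raises(ValueError):
                lagged.future_rows(origin, 12, persistence=False)
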