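"""NSD computation, sigmoid model fitting, migration metrics and timing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ANNUAL_SIGMOID_PARAMS, SPRING_SIGMOID_PARAMS, make_track
from nichetrack.nsd import (DoubleSigmoidNSD, SingleSigmoidNSD, compute_nsd,
                            derive_migration_metrics, double_sigmoid,
                            fit_double_sigmoid, fit_single_sigmoid,
                            project_to_plane, quantile_crossing,
                            segment_timing, single_sigmoid, thin_daily)

LN3 = np.log(3.0)


class TestNSDComputation:
    def test_first_fix_has_zero_nsd(self, small_track):
        nsd = compute_nsd(small_track)
        assert nsd["nsd_km2"].iloc[0] == 0.0

    def test_one_degree_north_of_equatorial_origin(self):
        tr = make_track([(0.0, 0.0), (0.0, 1.0)])
        nsd = compute_nsd(tr)
        assert nsd["nsd_km2"].iloc[1] == pytest.approx(12363.2, rel=2e-3)

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError, match="two fixes"):
            compute_nsd(make_track([(0.0, 0.0)]))

    def test_projection_round_trip_through_origin(self, small_track):
        planar = project_to_plane(small_track)
        assert planar["x_km"].iloc[0] == 0.0 and planar["y_km"].iloc[0] == 0.0


class TestSingleSigmoidFit:
    @pytest.mark.parametrize("bird", [5, 36])
    def test_noiseless_recovery(self, bird, spring_grid):
        delta, theta, phi = SPRING_SIGMOID_PARAMS[bird]
        y = single_sigmoid(spring_grid, delta, theta, phi)
        fit = SingleSigmoidNSD().fit(spring_grid, y)
        assert fit.converged_
        assert fit.delta_ == pytest.approx(delta, rel=1e-3)
        assert fit.theta_ == pytest.approx(theta, rel=1e-3)
        assert fit.phi_ == pytest.approx(phi, rel=1e-3)

    def test_constant_zero_series_flags_nonconvergence(self, spring_grid):
        fit = SingleSigmoidNSD().fit(spring_grid, np.zeros_like(spring_grid))
        assert not fit.converged_

    def test_noisy_recovery_of_asymptote(self):
        # Gaussian noise with SD 5% of delta: median relative error of the
        # fitted asymptote stays below 2% across seeds
        delta, theta, phi = SPRING_SIGMOID_PARAMS[16]
        t = np.arange(1.0, 250.0, 1.0)
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = single_sigmoid(t, delta, theta, phi) \
                + rng.normal(0.0, 0.05 * delta, size=t.size)
            fit = SingleSigmoidNSD().fit(t, y)
            errs.append(abs(fit.delta_ / delta - 1.0))
        assert np.median(errs) < 0.02

    def test_time_translation_shifts_only_theta(self, spring_grid):
        delta, theta, phi = SPRING_SIGMOID_PARAMS[20]
        y = single_sigmoid(spring_grid, delta, theta, phi)
        f0 = SingleSigmoidNSD().fit(spring_grid, y)
        f1 = SingleSigmoidNSD().fit(spring_grid + 37.0, y)
        assert f1.theta_ == pytest.approx(f0.theta_ + 37.0, abs=1e-6)
        assert f1.delta_ == pytest.approx(f0.delta_, rel=1e-8)
        assert f1.phi_ == pytest.approx(f0.phi_, rel=1e-6)


class TestDoubleSigmoidFit:
    def test_noiseless_recovery_all_parameters(self, annual_grid):
        p = ANNUAL_SIGMOID_PARAMS[22]
        y = double_sigmoid(annual_grid, *p)
        fit = DoubleSigmoidNSD().fit(annual_grid, y)
        assert fit.converged_
        est = (fit.delta_, fit.theta_s_, fit.theta_a_, fit.phi_s_, fit.phi_a_)
        for got, want in zip(est, p):
            assert got == pytest.approx(want, rel=5e-3)

    def test_curve_negligible_far_before_spring_midpoint(self):
        p = ANNUAL_SIGMOID_PARAMS[22]
        delta = p[0]
        assert double_sigmoid(30.0, *p) < 1e-3 * delta

    def test_round_trip_self_consistency(self, annual_grid):
        p = ANNUAL_SIGMOID_PARAMS[53]
        fit = DoubleSigmoidNSD().fit(annual_grid, double_sigmoid(annual_grid, *p))
        y2 = fit.predict(annual_grid)
        fit2 = DoubleSigmoidNSD().fit(annual_grid, y2)
        assert fit2.delta_ == pytest.approx(fit.delta_, rel=1e-6)
        assert fit2.theta_a_ == pytest.approx(fit.theta_a_, abs=1e-4)

    def test_missing_autumn_limb_flags_nonconvergence(self, spring_grid):
        delta, theta, phi = SPRING_SIGMOID_PARAMS[5]
        y = single_sigmoid(spring_grid, delta, theta, phi)  # rise only
        fit = DoubleSigmoidNSD().fit(spring_grid, y)
        assert not fit.converged_


@settings(deadline=None, derandomize=True, max_examples=40)
@given(delta=st.floats(1e4, 1e7), theta=st.floats(50.0, 200.0),
       phi=st.floats(0.1, 30.0))
def test_single_curve_properties(delta, theta, phi):
    """Monotone rise, half-asymptote at the midpoint, limits 0 and delta."""
    t = np.linspace(theta - 40 * phi, theta + 40 * phi, 500)
    y = single_sigmoid(t, delta, theta, phi)
    assert np.all(np.diff(y) >= 0)
    assert single_sigmoid(theta, delta, theta, phi) == pytest.approx(
        delta / 2, rel=1e-12)
    assert y[0] < 1e-6 * delta and y[-1] > (1 - 1e-6) * delta


class TestMetricsAndTiming:
    def test_two_phi_duration_surrogate(self, spring_grid):
        delta, theta, phi = SPRING_SIGMOID_PARAMS[16]
        fit = fit_single_sigmoid(pd.DataFrame({
            "t": spring_grid,
            "nsd_km2": single_sigmoid(spring_grid, delta, theta, phi)}))
        m = derive_migration_metrics(fit)
        assert m["two_phi_days"] == pytest.approx(16.86, abs=0.01)

    def test_sqrt_delta_distance_surrogate(self, spring_grid):
        delta, theta, phi = SPRING_SIGMOID_PARAMS[5]
        fit = fit_single_sigmoid(pd.DataFrame({
            "t": spring_grid,
            "nsd_km2": single_sigmoid(spring_grid, delta, theta, phi)}))
        m = derive_migration_metrics(fit)
        assert round(m["sqrt_delta_km"], 2) == 2314.29

    def test_quartile_span_is_two_phi_ln3(self):
        assert (quantile_crossing(100.0, 1.0, 0.75)
                - quantile_crossing(100.0, 1.0, 0.25)) == pytest.approx(
            2 * LN3, rel=1e-12)
        assert 2 * LN3 == pytest.approx(2.1972, abs=1e-4)

    def test_threshold_crossing_timing_closed_form(self, spring_grid):
        y = single_sigmoid(spring_grid, 1e6, 100.0, 5.0)
        fit = SingleSigmoidNSD().fit(spring_grid, y)
        tm = segment_timing(fit, frac=0.025)
        dep = 100.0 + 5.0 * np.log(0.025 / 0.975)
        assert tm.spring_departure == pytest.approx(dep, abs=1e-3)
        assert tm.spring_arrival == pytest.approx(200.0 - dep, abs=1e-3)
        assert tm.spring_duration == pytest.approx(2 * 5.0 * np.log(0.975 / 0.025),
                                                   abs=1e-3)

    def test_quarter_threshold_matches_quartile_span(self, spring_grid):
        y = single_sigmoid(spring_grid, 1e6, 100.0, 5.0)
        fit = SingleSigmoidNSD().fit(spring_grid, y)
        tm = segment_timing(fit, frac=0.25)
        assert tm.spring_duration == pytest.approx(2 * 5.0 * LN3, abs=1e-3)

    def test_double_fit_timing_orders_seasons(self, annual_grid):
        p = ANNUAL_SIGMOID_PARAMS[22]
        fit = fit_double_sigmoid(pd.DataFrame({
            "t": annual_grid, "nsd_km2": double_sigmoid(annual_grid, *p)}))
        tm = segment_timing(fit, t_span=(1.0, 365.0))
        assert (tm.spring_departure < tm.spring_arrival
                < tm.autumn_departure < tm.autumn_arrival)
        assert not tm.censored

    def test_invalid_frac_rejected(self, spring_grid):
        y = single_sigmoid(spring_grid, 1e6, 100.0, 5.0)
        fit = SingleSigmoidNSD().fit(spring_grid, y)
        with pytest.raises(ValueError):
            segment_timing(fit, frac=0.7)


class TestThinning:
    def test_one_fix_per_day_and_deterministic(self):
        rng = np.random.default_rng(2)
        n = 200
        ts = (pd.Timestamp("2001-03-01", tz="UTC")
              + pd.to_timedelta(np.sort(rng.uniform(0, 40 * 24, n)), unit="h"))
        tr = pd.DataFrame({"animal_id": "a", "timestamp": ts,
                           "lon": rng.normal(size=n), "lat": rng.normal(size=n),
                           "lc_class": pd.NA})
        thin = thin_daily(tr, seed=1)
        days = pd.to_datetime(thin["timestamp"]).dt.floor("D")
        assert days.is_unique
        pd.testing.assert_frame_equal(thin, thin_daily(tr, seed=1))
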