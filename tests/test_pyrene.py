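"""Bulk pyrene quantification: t_1/8 statistic, rates, and the Kd fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import formin_kinetics as fk
from formin_kinetics.pyrene import IncompleteReactionError
from formin_kinetics.simulate import simulate_bulk_from_slopes

from conftest import kd_grid_oracle, logistic_trace


class TestTimeToFraction:
    def test_logistic_closed_form(self):
        # F = P/8 at t0 - ln(7)/k for a logistic
        trc = logistic_trace(plateau=64.0, k=1.0, t0=50.0)
        expected = 50.0 - np.log(7.0)
        assert fk.time_to_fraction(trc) == pytest.approx(expected, abs=0.05)

    def test_half_completion_at_midpoint(self):
        trc = logistic_trace(plateau=64.0, k=1.0, t0=50.0)
        assert fk.time_to_fraction(trc, fraction=0.5) == pytest.approx(50.0, abs=0.01)

    def test_constant_trace_is_incomplete(self):
        t = np.arange(0.0, 100.0, 1.0)
        trc = fk.AssemblyTrace("flat", 0.0, t, np.full_like(t, 5.0),
                               baseline_au=5.0, plateau_au=100.0)
        with pytest.raises(IncompleteReactionError):
            fk.time_to_fraction(trc)

    def test_still_rising_trace_demands_explicit_plateau(self):
        t = np.arange(0.0, 100.0, 1.0)
        trc = fk.AssemblyTrace("rising", 0.0, t, 2.0 * t)
        with pytest.raises(ValueError, match="plateau"):
            fk.time_to_fraction(trc)


class TestSlopeAtTime:
    def test_linear_trace_any_time(self):
        t = np.arange(0.0, 200.0, 1.0)
        trc = fk.AssemblyTrace("lin", 0.0, t, 0.5 * t + 3.0)
        for at in (20.0, 100.0, 180.0):
            assert fk.slope_at_time(trc, at) == pytest.approx(0.5, rel=1e-9)

    def test_flat_trace_zero(self):
        t = np.arange(0.0, 100.0, 1.0)
        trc = fk.AssemblyTrace("flat", 0.0, t, np.full_like(t, 7.0))
        assert fk.slope_at_time(trc, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_seven_k_p_over_64_identity(self):
        # analytic slope at one-eighth completion is 7kP/64; measurable to a
        # few percent only when the window is short next to the curvature
        trc = logistic_trace(plateau=64.0, k=1.0, t0=50.0, dt=0.25)
        t18 = fk.time_to_fraction(trc)
        assert fk.slope_at_time(trc, t18, window_s=2.0) == pytest.approx(7.0, rel=0.10)

    def test_identity_exact_on_slow_fixture(self):
        # the deterministic fixture builder guarantees the slope analytically
        (trc,) = simulate_bulk_from_slopes([(10.0, 2.0)], plateau=5000.0)
        t18 = fk.time_to_fraction(trc)
        assert fk.slope_at_time(trc, t18) == pytest.approx(2.0, rel=0.01)

    def test_too_few_points_in_window(self):
        t = np.arange(0.0, 100.0, 10.0)
        trc = fk.AssemblyTrace("sparse", 0.0, t, t)
        with pytest.raises(ValueError, match="fewer than 4"):
            fk.slope_at_time(trc, 50.0, window_s=20.0)


class TestNucleationStrength:
    def test_exact_line_from_fixtures(self):
        # per-dose slopes 0.10 + 0.32*dose -> strength 0.32
        doses = [0.0, 5.0, 10.0]
        traces = simulate_bulk_from_slopes(
            [(d, 0.10 + 0.32 * d) for d in doses], plateau=5000.0
        )
        res = fk.nucleation_strength(traces)
        assert res.strength == pytest.approx(0.32, rel=0.01)
        assert res.intercept == pytest.approx(0.10, rel=0.05)
        assert len(res.per_dose) == 3

    def test_identical_slopes_give_zero_strength(self):
        traces = simulate_bulk_from_slopes(
            [(d, 1.5) for d in (0.0, 5.0, 10.0)], plateau=5000.0
        )
        res = fk.nucleation_strength(traces)
        assert res.strength == pytest.approx(0.0, abs=1e-3)

    def test_requires_three_doses(self):
        traces = simulate_bulk_from_slopes(
            [(0.0, 1.0), (5.0, 2.0)], plateau=5000.0
        )
        with pytest.raises(ValueError, match=">= 3 distinct"):
            fk.nucleation_strength(traces)

    def test_per_trace_failure_names_trace(self):
        traces = simulate_bulk_from_slopes(
            [(d, 0.1 + 0.3 * d) for d in (0.0, 5.0, 10.0)], plateau=5000.0
        )
        t = traces[1].time_s
        traces[1] = fk.AssemblyTrace("bad", 5.0, t, np.full_like(t, 2.0),
                                     baseline_au=2.0, plateau_au=5000.0)
        with pytest.raises(ValueError, match="bad"):
            fk.nucleation_strength(traces)


class TestInitialRateAndNormalization:
    def test_linear_rate(self):
        t = np.arange(0.0, 200.0, 1.0)
        trc = fk.AssemblyTrace("lin", 0.0, t, 2.0 * t)
        assert fk.initial_rate(trc) == pytest.approx(2.0)

    def test_window_excludes_flat_part(self):
        t = np.arange(0.0, 200.0, 1.0)
        sig = np.where(t <= 90, 2.0 * t, 180.0)
        trc = fk.AssemblyTrace("kink", 0.0, t, sig)
        assert fk.initial_rate(trc) == pytest.approx(2.0)

    def test_generator_round_trip_at_zero_formin(self):
        (trc,) = fk.simulate_seeded_elongation(1.0, 1.0, -4.5, 0.1, [0.0], v0=1.0)
        assert fk.initial_rate(trc) == pytest.approx(1.0, rel=0.02)

    def test_short_trace_warns(self):
        with pytest.warns(UserWarning, match="90 s"):
            fk.simulate_seeded_elongation(1.0, 1.0, -4.5, 0.1, [0.0], duration=60.0)

    def test_normalize(self):
        out = fk.normalize_rates([(0.0, 4.0), (1.0, 1.0), (2.0, 6.0)], 4.0)
        assert out == [(0.0, 1.0), (1.0, 0.25), (2.0, 1.5)]  # r>1 preserved

    def test_normalize_rejects_bad_control(self):
        with pytest.raises(ValueError):
            fk.normalize_rates([(0.0, 1.0)], 0.0)

    def test_normalization_idempotent_with_unit_control(self):
        rates = [(0.0, 1.0), (1.0, 0.4)]
        assert fk.normalize_rates(rates, 1.0) == rates


class TestQuadraticBindingRate:
    def test_hand_value(self):
        # r = 1 - 5*(0.3 - sqrt(0.05))
        r = fk.quadratic_binding_rate(0.1, B=0.1, kd=0.1, a=1.0, b=-5.0)
        assert r == pytest.approx(0.618034, abs=1e-6)

    @given(
        B=st.floats(0.01, 10.0),
        kd=st.floats(0.001, 100.0),
        a=st.floats(0.5, 2.0),
        b=st.floats(-10.0, -0.1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_limits(self, B, kd, a, b):
        assert fk.quadratic_binding_rate(0.0, B, kd, a, b) == pytest.approx(a)
        limit = a + 2.0 * b * B
        assert abs(fk.quadratic_binding_rate(1e6 * kd, B, kd, a, b) - limit) < 1e-3

    @given(kd=st.floats(0.01, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_decreasing_for_negative_b(self, kd):
        F = np.geomspace(1e-3, 1e3, 50)
        r = fk.quadratic_binding_rate(F, 0.1, kd, 1.0, -4.5)
        assert np.all(np.diff(r) <= 1e-12)


class TestBarbedEndAffinityFit:
    def test_noise_free_round_trip_and_grid_oracle(self):
        F = np.concatenate([[0.0], 0.03 * 2.0 ** np.arange(11)])  # 0.03-61 nM
        r = fk.quadratic_binding_rate(F, 0.1, 1.0, 1.0, -4.5)
        fit = fk.fit_barbed_end_affinity(list(zip(F, r)), 0.1)
        assert fit.kd_nM == pytest.approx(1.0, rel=0.02)
        oracle = kd_grid_oracle(
            F, r, 0.1,
            np.geomspace(0.005, 50.0, 200),
            np.linspace(0.8, 1.2, 200),
            np.linspace(-8.0, -1.0, 200),
        )
        assert fit.kd_nM == pytest.approx(oracle[0], rel=0.05)

    def test_fitter_matches_grid_on_random_draws(self, rng):
        kd_grid = np.geomspace(0.005, 50.0, 200)
        a_grid = np.linspace(0.8, 1.2, 200)
        b_grid = np.linspace(-8.0, -1.0, 200)
        grid_step = kd_grid[1] / kd_grid[0] - 1.0
        for _ in range(20):
            kd = float(10 ** rng.uniform(-2, 1))
            a = float(rng.uniform(0.9, 1.1))
            b = float(rng.uniform(-6.0, -2.0))
            F = np.concatenate([[0.0], kd * np.geomspace(0.05, 80.0, 12)])
            r = fk.quadratic_binding_rate(F, 0.1, kd, a, b)
            fit = fk.fit_barbed_end_affinity(list(zip(F, r)), 0.1)
            oracle_kd = kd_grid_oracle(F, r, 0.1, kd_grid, a_grid, b_grid)[0]
            assert abs(fit.kd_nM - oracle_kd) / oracle_kd < 2 * grid_step

    def test_recovery_under_noise(self, rng):
        # 5% Gaussian noise on r, 3 replicates: median relative error < 15%
        errors = []
        for kd in (0.023, 0.218, 0.470, 0.750, 4.9):
            F = np.concatenate([[0.0], kd * np.geomspace(0.1, 100.0, 10)])
            r_true = fk.quadratic_binding_rate(F, 0.1, kd, 1.0, -4.5)
            pts = []
            for _ in range(3):
                r_obs = r_true * (1 + rng.normal(0, 0.05, size=F.size))
                pts.extend(zip(F, r_obs))
            fit = fk.fit_barbed_end_affinity(pts, 0.1)
            errors.append(abs(fit.kd_nM - kd) / kd)
        assert np.median(errors) < 0.15

    def test_flat_response_flags_unidentifiable(self):
        pts = [(f, 1.0) for f in (0.0, 0.1, 1.0, 10.0, 100.0)]
        fit = fk.fit_barbed_end_affinity(pts, 0.1)
        assert fit.kd_at_bound

    def test_needs_four_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            fk.fit_barbed_end_affinity([(0.0, 1.0), (1.0, 0.5), (2.0, 0.4)], 0.1)

    def test_estimator_predict_matches_model(self):
        F = np.concatenate([[0.0], np.geomspace(0.05, 50.0, 9)])
        r = fk.quadratic_binding_rate(F, 0.1, 0.5, 1.0, -4.5)
        est = fk.BarbedEndAffinityFit(barbed_ends_nM=0.1).fit(F, r)
        assert np.allclose(est.predict(F), r, atol=1e-6)
        # sklearn param plumbing
        assert est.get_params()["barbed_ends_nM"] == 0.1
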