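import numpy as np
import pytest

import respcomp as rc
from _oracles import dominant_period_fft, scan_cycle_displacements
from respcomp.compensation import (
    cycle_minima,
    dominant_period,
    lagged_sine_residual_amplitude,
)
from respcomp.errors import AlignmentError, DegenerateTraceError, ParameterError


class TestSimulateCouch:
    def test_zero_latency_is_exact_inverse(self):
        tr = rc.gen_sine(10, 4, 20)
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=0))
        np.testing.assert_allclose(couch.values, -tr.values, atol=1e-12)
        res = rc.residual(tr, couch)
        assert np.max(np.abs(res.values)) < 1e-12

    def test_lagged_sine_residual_matches_closed_form(self):
        # residual of a lagged inverted sinusoid: 2*A*sin(pi*L/T)
        A, T, L = 15.0, 4.0, 0.047
        tr = rc.gen_sine(A, T, 60, dt=0.01)
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=L))
        res = rc.residual(tr, couch)
        expected = lagged_sine_residual_amplitude(A, T, L)
        assert expected == pytest.approx(1.1072, abs=2e-4)
        assert np.max(np.abs(res.values)) == pytest.approx(expected, rel=1e-3)

    def test_constant_command_gives_constant_couch(self):
        tr = rc.Trace(0, 0.01, np.full(500, 4.0))
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=0.047))
        np.testing.assert_allclose(couch.values, -4.0)

    def test_gain_error_scales_couch(self):
        tr = rc.gen_sine(10, 4, 12)
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=0, gain_error=0.1))
        np.testing.assert_allclose(couch.values, -1.1 * tr.values, atol=1e-12)

    def test_max_speed_limits_step(self):
        tr = rc.gen_sine(15, 4, 12)
        couch = rc.simulate_couch(
            tr, rc.CompensationConfig(latency=0, max_speed=5.0)
        )
        steps = np.abs(np.diff(couch.values))
        assert steps.max() <= 5.0 * tr.dt + 1e-12

    def test_noise_is_seed_deterministic(self):
        tr = rc.gen_sine(10, 4, 12)
        cfg = rc.CompensationConfig(actuator_noise_sd=0.5, seed=3)
        a = rc.simulate_couch(tr, cfg)
        b = rc.simulate_couch(tr, cfg)
        np.testing.assert_array_equal(a.values, b.values)


class TestResidualAndErrors:
    def test_uncompensated_arm_residual_is_target(self):
        tr = rc.gen_sine(5, 4, 12)
        zero = tr.with_values(np.zeros(tr.n))
        np.testing.assert_array_equal(rc.residual(tr, zero).values, tr.values)

    def test_length_mismatch_rejected(self):
        a = rc.Trace(0, 0.01, np.zeros(10) + np.arange(10.0))
        b = rc.Trace(0, 0.01, np.arange(12.0))
        with pytest.raises(AlignmentError):
            rc.residual(a, b)

    def test_perfect_tracking_zero_error(self):
        tr = rc.gen_sine(5, 4, 12)
        assert rc.position_error(tr, tr) == 0.0

    def test_constant_offset_error(self):
        tr = rc.gen_sine(5, 4, 12)
        shifted = tr.with_values(tr.values + 1.0)
        assert rc.position_error(tr, shifted) == pytest.approx(1.0)

    def test_gaussian_noise_gives_folded_normal_mean(self, rng):
        # E|N(0, sd)| = sd * sqrt(2/pi); sd = 1.25 gives 0.997
        n = 10_000
        tr = rc.Trace(0, 0.01, np.zeros(n))
        noisy = tr.with_values(rng.normal(0, 1.25, n))
        expected = 1.25 * np.sqrt(2 / np.pi)
        assert expected == pytest.approx(0.997, abs=1e-3)
        assert rc.position_error(tr, noisy) == pytest.approx(expected, rel=0.03)

    def test_translation_invariance(self, rng):
        n = 2000
        a = rc.Trace(0, 0.01, rng.normal(0, 2, n))
        b = rc.Trace(0, 0.01, rng.normal(0, 2, n))
        base = rc.position_error(a, b)
        shifted = rc.position_error(
            a.with_values(a.values + 7.3), b.with_values(b.values + 7.3)
        )
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_rms_and_max_statistics(self):
        tr = rc.Trace(0, 0.01, np.zeros(4))
        other = tr.with_values(np.array([0.0, 3.0, -4.0, 0.0]))
        assert rc.position_error(tr, other, stat="max") == 4.0
        assert rc.position_error(tr, other, stat="rms") == pytest.approx(np.sqrt(25 / 4))


class TestCompensationRate:
    @pytest.mark.parametrize(
        "target_mean, residual_mean, expected",
        [(7.67, 1.92, 75.0), (21.39, 7.00, 67.3), (9.50, 2.44, 74.3)],
    )
    def test_reference_study_rates(self, target_mean, residual_mean, expected):
        assert round(rc.compensation_rate(target_mean, residual_mean), 1) == expected

    def test_zero_residual_is_full_compensation(self):
        assert rc.compensation_rate(12.3, 0.0) == 100.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ParameterError):
            rc.compensation_rate(0.0, 1.0)

    def test_rate_never_exceeds_100(self):
        for t, r in [(5, 0.1), (20, 19), (1, 1)]:
            assert rc.compensation_rate(t, r) <= 100.0


class TestCycleSegmentation:
    def test_pure_sine_cycles(self):
        tr = rc.gen_sine(5, 4, 20, dt=0.01)
        pps = rc.cycle_displacements(tr)
        assert len(pps) >= 3
        np.testing.assert_allclose(pps, 10.0, atol=1e-3)

    def test_dominant_period_matches_fft_oracle(self):
        tr = rc.gen_breathing(
            rc.BreathingParams(displacement_pp=20, amplitude_cv=0.2, seed=3)
        )
        p_ac = dominant_period(tr)
        p_fft = dominant_period_fft(tr.values, tr.dt)
        assert p_ac == pytest.approx(p_fft, rel=0.15)

    def test_breathing_segmentation_matches_minima_scan(self):
        tr = rc.gen_breathing(
            rc.BreathingParams(displacement_pp=20, amplitude_cv=0.2, seed=3)
        )
        pps = rc.cycle_displacements(tr)
        min_sep = int(round(0.5 * dominant_period(tr) / tr.dt))
        pps_oracle, _ = scan_cycle_displacements(tr.values, min_sep)
        assert np.mean(pps) == pytest.approx(np.mean(pps_oracle), rel=1e-6)

    def test_constant_trace_rejected(self):
        tr = rc.Trace(0, 0.01, np.full(1000, 2.0))
        with pytest.raises(DegenerateTraceError):
            rc.cycle_displacements(tr)

    def test_minima_are_separated(self):
        tr = rc.gen_breathing(rc.BreathingParams(displacement_pp=30, seed=9))
        minima = cycle_minima(tr)
        assert np.all(np.diff(minima) * tr.dt >= 0.5 * dominant_period(tr) - tr.dt)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = rc.Trace(0, 0.01, np.linspace(0, 1, 100))
        y = x.with_values(2 * x.values + 1)
        assert rc.pearson(x, y) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = rc.Trace(0, 0.01, np.sin(np.linspace(0, 20, 300)))
        y = x.with_values(-x.values)
        assert rc.pearson(x, y) == pytest.approx(-1.0)

    def test_constructed_correlation_recovered(self, rng):
        # y = r*x + sqrt(1-r^2)*z with x,z iid standard normal has corr r
        n, r = 6000, 0.95
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = r * x + np.sqrt(1 - r**2) * z
        got = rc.pearson(rc.Trace(0, 0.01, x), rc.Trace(0, 0.01, y))
        assert got == pytest.approx(r, abs=0.01)

    def test_zero_variance_rejected(self):
        x = rc.Trace(0, 0.01, np.full(10, 1.0))
        y = rc.Trace(0, 0.01, np.arange(10.0))
        with pytest.raises(DegenerateTraceError):
            rc.pearson(x, y)


class TestKinematicsReport:
    def test_ideal_compensation_rates_100(self):
        tr = rc.gen_breathing(rc.BreathingParams(displacement_pp=20, seed=5, duration=40))
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=0))
        rep = rc.kinematics_report(tr, couch)
        assert rep.comp_rate_mean == pytest.approx(100.0, abs=1e-9)
        assert rep.compensating_error < 1e-12
        assert rep.pearson_r == pytest.approx(1.0)

    def test_latency_only_reduces_rate_below_100(self):
        tr = rc.gen_sine(15, 4, 44.4)
        couch = rc.simulate_couch(tr, rc.CompensationConfig(latency=0.047))
        rep = rc.kinematics_report(tr, couch)
        assert 80.0 < rep.comp_rate_mean < 100.0
        assert rep.target_mean_disp == pytest.approx(30.0, abs=0.01)
        assert -1 <= rep.pearson_r <= 1
        assert list(rep.per_cycle.columns) == [
            "cycle",
            "target_pp_mm",
            "residual_pp_mm",
            "rate_pct",
        ]
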