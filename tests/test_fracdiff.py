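"""Fractional-derivative operator, cycle averages and alpha estimators."""

import numpy as np
import pytest

from glmadapt import fracdiff, hh
from glmadapt.stimulus import EnvelopeSpec, envelope_value
from tests.conftest import poisson_spike_train


def sine_response_gain_phase(alpha, f, n=4096, cycles=8):
    """Apply the GL operator to a fine-grained sinusoid; return measured
    (gain, phase lead) of the output relative to the input."""
    dt = cycles / (f * n * cycles) * cycles  # n samples per cycle
    dt = 1.0 / (f * n)
    t = np.arange(n * cycles) * dt
    x = np.sin(2 * np.pi * f * t)
    y = fracdiff.fractional_derivative(x, alpha, dt)
    # measure on the last cycle (transient-free)
    tail = slice(-n, None)
    tt, yy = t[tail], y[tail]
    a = 2.0 * np.mean(yy * np.sin(2 * np.pi * f * tt))
    b = 2.0 * np.mean(yy * np.cos(2 * np.pi * f * tt))
    return np.hypot(a, b), np.arctan2(b, a)


class TestFractionalDerivative:
    def test_order_zero_is_identity(self):
        x = np.sin(np.linspace(0, 10, 500))
        assert np.allclose(fracdiff.fractional_derivative(x, 0.0, 0.01), x)

    def test_order_one_differentiates_quadratic(self):
        dt = 0.001
        t = np.arange(5000) * dt
        y = fracdiff.fractional_derivative(t**2, 1.0, dt)
        interior = slice(100, -100)
        assert np.allclose(y[interior], 2 * t[interior], rtol=0.01, atol=1e-3)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_sinusoid_gain_and_phase_closed_form(self, alpha):
        """On sin(2*pi*f*t): amplitude gain (2*pi*f)^alpha and phase lead
        alpha*pi/2."""
        f = 2.0
        gain, phase = sine_response_gain_phase(alpha, f)
        assert gain == pytest.approx((2 * np.pi * f) ** alpha, rel=0.01)
        assert phase == pytest.approx(alpha * np.pi / 2, abs=0.01)

    def test_frequency_scaling_of_gain(self):
        alpha = 0.4
        g1, _ = sine_response_gain_phase(alpha, 1.0)
        g4, _ = sine_response_gain_phase(alpha, 4.0)
        assert g4 / g1 == pytest.approx(4.0**alpha, rel=0.01)

    def test_half_derivative_composes_to_first_derivative(self):
        """FD_0.5 applied twice acts like d/dt on a smooth periodic signal."""
        n = 2000
        dt = 1.0 / n
        t = np.arange(n) * dt
        x = np.sin(2 * np.pi * t)
        once = fracdiff.fractional_derivative(x, 0.5, dt, periodic=True)
        twice = fracdiff.fractional_derivative(once, 0.5, dt, periodic=True)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.allclose(twice, expected, rtol=0.02, atol=0.05 * 2 * np.pi)

    def test_periodic_wrap_matches_steady_state(self):
        n = 1024
        dt = 1.0 / n
        t = np.arange(n) * dt
        x = np.sin(2 * np.pi * t)
        y = fracdiff.fractional_derivative(x, 0.3, dt, periodic=True)
        a = 2.0 * np.mean(y * np.sin(2 * np.pi * t))
        b = 2.0 * np.mean(y * np.cos(2 * np.pi * t))
        assert np.hypot(a, b) == pytest.approx((2 * np.pi) ** 0.3, rel=0.01)
        assert np.arctan2(b, a) == pytest.approx(0.3 * np.pi / 2, abs=0.01)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            fracdiff.fractional_derivative(np.ones(10), 1.5, 0.01)


class TestCycleAverage:
    def test_homogeneous_poisson_is_flat_within_error(self):
        spikes = poisson_spike_train(lambda t: 10.0, 400.0, seed=30)
        ca = fracdiff.cycle_average(spikes, period=2.0, discard_cycles=2)
        # each bin: ~198 cycles x 66.7 ms x 10 spk/s = 132 expected counts
        n_cycles = ca.n_cycles
        expect = 10.0
        se = np.sqrt(expect / (n_cycles * (2.0 / 30)))
        assert np.max(np.abs(ca.rates - expect)) < 4.5 * se

    def test_sinusoidal_rate_first_harmonic_recovered(self):
        p = 2.0
        spikes = poisson_spike_train(
            lambda t: 10.0 + 5.0 * np.sin(2 * np.pi * t / p), 600.0, seed=31
        )
        ca = fracdiff.cycle_average(spikes, period=p, discard_cycles=2)
        gain, phase = fracdiff.extract_gain_phase(ca)
        assert gain == pytest.approx(5.0, rel=0.1)
        assert phase == pytest.approx(0.0, abs=0.1)

    def test_spike_on_bin_edge_goes_to_right_closed_bin(self):
        # phase bins are left-closed: a spike exactly at a bin edge lands in
        # the bin starting at that edge
        period = 3.0
        t_edge = 2 * period + period / 30  # edge of bin 1 after burn-in
        spikes = hh.SpikeTrain(spike_times=np.array([t_edge]),
                               duration=4 * period)
        ca = fracdiff.cycle_average(spikes, period, discard_cycles=2)
        assert ca.rates[1] > 0
        assert ca.rates[0] == 0

    def test_too_short_duration_rejected(self):
        spikes = poisson_spike_train(lambda t: 10.0, 5.0, seed=32)
        with pytest.raises(ValueError):
            fracdiff.cycle_average(spikes, period=2.0, discard_cycles=2)


class TestGainPhaseExtraction:
    def test_exact_single_harmonic_identity(self):
        theta = 2 * np.pi * (np.arange(30) + 0.5) / 30
        for g0, phi0 in ((3.0, 0.7), (1.5, -0.4)):
            rates = 8.0 + g0 * np.sin(theta + phi0)
            ca = fracdiff.CycleAverage(rates=rates, period=2.0, n_bins=30,
                                       n_cycles=50)
            g, phi = fracdiff.extract_gain_phase(ca)
            assert g == pytest.approx(g0, rel=1e-9)
            assert phi == pytest.approx(phi0, rel=1e-9)

    def test_rate_proportional_to_envelope_has_zero_phase(self):
        env = EnvelopeSpec("sine", period_p=4.0, sigma=2.0)
        t = (np.arange(30) + 0.5) * (4.0 / 30)
        rates = 10.0 * envelope_value(env, t)
        ca = fracdiff.CycleAverage(rates=rates, period=4.0, n_bins=30,
                                   n_cycles=50, envelope=env)
        _, phi = fracdiff.extract_gain_phase(ca)
        assert phi == pytest.approx(0.0, abs=1e-6)

    def test_fractional_derivative_of_envelope_leads_by_alpha_pi_over_2(self):
        alpha = 0.35
        env = EnvelopeSpec("sine", period_p=4.0, sigma=2.0)
        t = (np.arange(30) + 0.5) * (4.0 / 30)
        e = envelope_value(env, t)
        fd = fracdiff.fractional_derivative(e, alpha, 4.0 / 30, periodic=True)
        ca = fracdiff.CycleAverage(rates=10.0 + fd, period=4.0, n_bins=30,
                                   n_cycles=50, envelope=env)
        _, phi = fracdiff.extract_gain_phase(ca)
        assert phi == pytest.approx(alpha * np.pi / 2, abs=0.04)

    def test_flat_cycle_average_has_undefined_phase(self):
        ca = fracdiff.CycleAverage(rates=np.full(30, 7.0), period=1.0,
                                   n_bins=30, n_cycles=50)
        with pytest.raises(ValueError, match="phase"):
            fracdiff.extract_gain_phase(ca)


class TestAlphaEstimators:
    def test_gain_slope_recovers_exact_power_law(self):
        periods = np.array([1.0, 2.0, 4.0, 8.0])
        gains = (1.0 / periods) ** 0.5
        assert fracdiff.alpha_from_gain(periods, gains) == pytest.approx(0.5)
        assert fracdiff.alpha_from_gain(periods, np.ones(4)) == pytest.approx(0.0)

    def test_phase_estimator_closed_form(self):
        assert fracdiff.alpha_from_phase(np.full(5, np.pi / 4)) == \
            pytest.approx(0.5)
        assert fracdiff.alpha_from_phase(np.zeros(3)) == pytest.approx(0.0)

    @pytest.mark.parametrize("alpha", [0.1, 0.2, 0.4])
    def test_estimators_agree_on_exact_operator_output(self, alpha):
        """All three estimators within 0.05 of the generating order when the
        rates are exact fractional derivatives of the envelope."""
        periods = [1.0, 2.0, 4.0, 8.0, 16.0]
        gains, phases, cas = [], [], []
        for p in periods:
            t = (np.arange(30) + 0.5) * (p / 30)
            env_sin = EnvelopeSpec("sine", period_p=p, sigma=2.0)
            fd = fracdiff.fractional_derivative(
                envelope_value(env_sin, t), alpha, p / 30, periodic=True)
            ca = fracdiff.CycleAverage(rates=10.0 + 3.0 * fd, period=p,
                                       n_bins=30, n_cycles=50,
                                       envelope=env_sin)
            g, ph = fracdiff.extract_gain_phase(ca)
            gains.append(g)
            phases.append(ph)
            env_sq = EnvelopeSpec("square", period_p=p, sigma=2.0)
            fd_sq = fracdiff.fractional_derivative(
                envelope_value(env_sq, t), alpha, p / 30, periodic=True)
            cas.append(fracdiff.CycleAverage(
                rates=10.0 + 3.0 * fd_sq, period=p, n_bins=30, n_cycles=50,
                envelope=env_sq))
        a_gain = fracdiff.alpha_from_gain(np.array(periods), np.array(gains))
        a_phase = fracdiff.alpha_from_phase(np.array(phases))
        a_sq, _, _ = fracdiff.alpha_from_square(cas)
        for est in (a_gain, a_phase, a_sq):
            assert abs(est - alpha) <= 0.05

    def test_square_fit_self_consistency(self):
        """Responses generated as exact FD_0.25(envelope) + baseline are
        recovered to within 0.01."""
        cas = []
        for p in (1.0, 2.0, 4.0, 8.0):
            env = EnvelopeSpec("square", period_p=p, sigma=2.0)
            t = (np.arange(30) + 0.5) * (p / 30)
            fd = fracdiff.fractional_derivative(
                envelope_value(env, t), 0.25, p / 30, periodic=True)
            cas.append(fracdiff.CycleAverage(
                rates=5.0 + 2.0 * fd, period=p, n_bins=30, n_cycles=50,
                envelope=env))
        alpha, scale, base = fracdiff.alpha_from_square(cas)
        assert alpha == pytest.approx(0.25, abs=0.01)
        assert scale == pytest.approx(2.0, rel=0.05)

    def test_square_fit_on_envelope_itself_gives_zero(self):
        cas = []
        for p in (1.0, 2.0, 4.0):
            env = EnvelopeSpec("square", period_p=p, sigma=2.0)
            t = (np.arange(30) + 0.5) * (p / 30)
            cas.append(fracdiff.CycleAverage(
                rates=4.0 * envelope_value(env, t), period=p, n_bins=30,
                n_cycles=50, envelope=env))
        alpha, _, _ = fracdiff.alpha_from_square(cas)
        assert alpha == pytest.approx(0.0, abs=0.02)

    def test_square_fit_beats_grid_scan(self):
        """The returned alpha is at least as good as a 101-point grid."""
        rng = np.random.default_rng(33)
        cas = []
        for p in (1.0, 4.0):
            env = EnvelopeSpec("square", period_p=p, sigma=2.0)
            t = (np.arange(30) + 0.5) * (p / 30)
            fd = fracdiff.fractional_derivative(
                envelope_value(env, t), 0.3, p / 30, periodic=True)
            cas.append(fracdiff.CycleAverage(
                rates=5.0 + 2.0 * fd + 0.3 * rng.standard_normal(30),
                period=p, n_bins=30, n_cycles=50, envelope=env))
        alpha, _, _ = fracdiff.alpha_from_square(cas)
        envs = [ca.envelope for ca in cas]
        sse_best = fracdiff._square_fit_sse(alpha, cas, envs)[0]
        grid_sses = [fracdiff._square_fit_sse(a, cas, envs)[0]
                     for a in np.linspace(0, 1, 101)]
        assert sse_best <= min(grid_sses) + 1e-9

    def test_flat_responses_unidentifiable(self):
        env = EnvelopeSpec("square", period_p=2.0, sigma=2.0)
        cas = [fracdiff.CycleAverage(rates=np.full(30, 5.0), period=2.0,
                                     n_bins=30, n_cycles=50, envelope=env)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fracdiff.alpha_from_square(cas)


class TestExponentialTimescale:
    def test_recovers_known_time_constant(self):
        p = 8.0
        t = (np.arange(30) + 0.5) * (p / 30)
        tau = 0.5
        rates = np.empty(30)
        half = p / 2
        rates[:15] = 12.0 + 6.0 * np.exp(-t[:15] / tau)
        rates[15:] = 12.0 - 6.0 * np.exp(-(t[15:] - half) / tau)
        ca = fracdiff.CycleAverage(rates=rates, period=p, n_bins=30,
                                   n_cycles=50)
        tau_up, tau_down = fracdiff.fit_exponential_timescale(ca)
        assert tau_up == pytest.approx(tau, rel=0.02)
        assert tau_down == pytest.approx(tau, rel=0.02)

    def test_invariant_to_baseline_shift(self):
        p = 4.0
        t = (np.arange(30) + 0.5) * (p / 30)
        rates = 3.0 * np.exp(-np.minimum(t % (p / 2), p / 2) / 0.4)
        rates = np.concatenate([rates[:15] + 5.0, rates[15:] + 5.0])
        ca1 = fracdiff.CycleAverage(rates=rates, period=p, n_bins=30,
                                    n_cycles=50)
        ca2 = fracdiff.CycleAverage(rates=rates + 20.0, period=p, n_bins=30,
                                    n_cycles=50)
        t1 = fracdiff.fit_exponential_timescale(ca1)
        t2 = fracdiff.fit_exponential_timescale(ca2)
        assert t1[0] == pytest.approx(t2[0], rel=1e-3)
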