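"""Fractional differentiation of the stimulus variance envelope.

Neurons with slow AHP currents respond to periodic modulation of the noise
SD like a fractional differentiator of order alpha: on a sinusoidal envelope
of frequency f the response gain grows as f^alpha and the phase leads the
envelope by the frequency-independent angle alpha*pi/2; on a square envelope
the response decays exponentially after each step with a time constant that
grows with the period.

This module provides the reference discrete fractional-derivative operator
(Grunwald-Letnikov), cycle averaging of spike trains, first-harmonic
gain/phase extraction, exponential time-constant fits, and the three
estimators of alpha (from gain-vs-frequency slope, from mean phase lead,
and from a least-squares fractional-derivative fit to square-wave cycle
averages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .hh import SpikeTrain
from .stimulus import EnvelopeSpec, envelope_value

__all__ = [
    "CycleAverage",
    "FracDiffResult",
    "fractional_derivative",
    "cycle_average",
    "extract_gain_phase",
    "alpha_from_gain",
    "alpha_from_phase",
    "alpha_from_square",
    "fit_exponential_timescale",
]


@dataclass(frozen=True)
class CycleAverage:
    """Mean firing rate in phase bins across cycles of the SD envelope."""

    rates: np.ndarray  # spk/s per phase bin
    period: float  # s
    n_bins: int
    n_cycles: int
    envelope: EnvelopeSpec | None = None

    def phases(self) -> np.ndarray:
        """Bin-center phase in [0, 1) cycle units."""
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def times(self) -> np.ndarray:
        """Bin-center time within the cycle, seconds."""
        return self.phases() * self.period


@dataclass(frozen=True)
class FracDiffResult:
    """Per-period sinusoid metrics and the three alpha estimates."""

    periods: tuple[float, ...]
    gains: np.ndarray
    phases: np.ndarray  # phase lead, radians, in (-pi, pi]
    alpha_gain: float
    alpha_phase: float
    alpha_square: float | None
    sigma: float


def _gl_weights(alpha: float, n: int) -> np.ndarray:
    """Grunwald-Letnikov binomial weights (-1)^k C(alpha, k), k = 0..n-1."""
    w = np.empty(n)
    w[0] = 1.0
    for k in range(1, n):
        w[k] = w[k - 1] * (k - 1 - alpha) / k
    return w


def fractional_derivative(
    signal: np.ndarray, alpha: float, dt: float, periodic: bool = False
) -> np.ndarray:
    """Discrete fractional derivative of order alpha (Grunwald-Letnikov).

    ``alpha = 0`` is the identity and ``alpha = 1`` approximates the first
    derivative.  With ``periodic=True`` the convolution wraps around the
    signal (treated as one period of a periodic waveform), which gives the
    steady-state response: on sin(2*pi*f*t) the output is
    (2*pi*f)^alpha * sin(2*pi*f*t + alpha*pi/2).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    if periodic:
        # wrap the GL memory around the period; sum the weight tail onto one
        # period so the operator is exactly circulant with converged weights
        n_rep = max(1, int(np.ceil(2000.0 / n)) + 1)
        w = _gl_weights(alpha, n * n_rep + n)
        w_fold = np.zeros(n)
        for r in range(n_rep + 1):
            w_fold += w[r * n : (r + 1) * n]
        out = np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(w_fold)))
    else:
        w = _gl_weights(alpha, n)
        out = np.convolve(x, w)[:n]
    return out / dt**alpha


def cycle_average(
    spikes: SpikeTrain,
    period: float,
    n_bins: int = 30,
    discard_cycles: int = 2,
    envelope: EnvelopeSpec | None = None,
) -> CycleAverage:
    """Mean rate in ``n_bins`` phase bins across cycles of length ``period``.

    The first ``discard_cycles`` cycles are treated as burn-in.  A trailing
    partial cycle is dropped.  Spikes exactly on a bin edge fall in the bin
    to the right (left-closed bins).
    """
    n_cycles_total = int(np.floor(spikes.duration / period + 1e-9))
    n_cycles = n_cycles_total - discard_cycles
    if n_cycles < 2:
        raise ValueError(
            f"duration {spikes.duration} s gives {n_cycles} usable cycles "
            f"of {period} s; need >= 2"
        )
    t0 = discard_cycles * period
    t1 = t0 + n_cycles * period
    st = spikes.spike_times
    st = st[(st >= t0) & (st < t1)]
    phase = ((st - t0) / period) % 1.0
    f = phase * n_bins
    # left-closed bins: snap values within round-off of a bin edge upward so
    # a spike exactly on an edge lands in the bin starting there
    f = np.where(np.ceil(f) - f < 1e-9 * n_bins, np.ceil(f), f)
    idx = np.minimum(np.floor(f).astype(np.int64) % n_bins, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    bin_dur = period / n_bins
    rates = counts / (n_cycles * bin_dur)
    return CycleAverage(
        rates=rates, period=period, n_bins=n_bins, n_cycles=n_cycles,
        envelope=envelope,
    )


def extract_gain_phase(ca: CycleAverage) -> tuple[float, float]:
    """First-harmonic amplitude and phase lead of a sine-envelope response.

    Fits r(theta) ~ c + g*sin(theta + phi) to the cycle average, where theta
    is the envelope's sine phase (theta = 0 at the start of the cycle).
    Returns (g, phi) with phi in (-pi, pi]; positive phi is a phase lead.
    """
    r = ca.rates
    theta = 2.0 * np.pi * ca.phases()
    a = 2.0 * np.mean(r * np.sin(theta))  # g*cos(phi)
    b = 2.0 * np.mean(r * np.cos(theta))  # g*sin(phi)
    gain = float(np.hypot(a, b))
    if gain < 1e-12:
        raise ValueError("zero modulation: phase undefined")
    phase = float(np.arctan2(b, a))
    return gain, phase


def alpha_from_gain(
    periods: np.ndarray, gains: np.ndarray
) -> float:
    """Slope of log(gain) on log(f): an order-alpha differentiator has
    gain proportional to f^alpha."""
    periods = np.asarray(periods, dtype=float)
    gains = np.asarray(gains, dtype=float)
    ok = gains > 0
    if (~ok).any():
        import warnings

        warnings.warn("non-positive gains excluded from the log-log fit",
                      stacklevel=2)
    periods, gains = periods[ok], gains[ok]
    if len(gains) < 3:
        raise ValueError("need >= 3 positive gains across frequencies")
    logf = np.log(1.0 / periods)
    slope = np.polyfit(logf, np.log(gains), 1)[0]
    return float(slope)


def alpha_from_phase(phases: np.ndarray) -> float:
    """alpha = 2 * mean(phase lead) / pi (phase lead is alpha*pi/2)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    return float(2.0 * np.mean(phases) / np.pi)


def _square_fit_sse(alpha, cas, envelopes, pooled_baseline=True):
    """SSE of scale*FD_alpha(envelope) + baseline against all cycle averages.

    scale and baseline are profiled out by linear least squares at each
    alpha; periods are weighted equally (each cycle average contributes its
    n_bins residuals once).
    """
    preds, obs = [], []
    for ca, env in zip(cas, envelopes):
        t = ca.times()
        e = envelope_value(env, t)
        fd = fractional_derivative(e, alpha, ca.period / ca.n_bins, periodic=True)
        preds.append(fd)
        obs.append(ca.rates)
    preds = np.concatenate(preds)
    obs = np.concatenate(obs)
    X = np.column_stack([preds, np.ones_like(preds)])
    coef, _, _, _ = np.linalg.lstsq(X, obs, rcond=None)
    resid = obs - X @ coef
    return float(resid @ resid), coef


def alpha_from_square(
    cas: list[CycleAverage],
    envelopes: list[EnvelopeSpec] | None = None,
) -> tuple[float, float, float]:
    """Best-fitting fractional-derivative order for square-wave responses.

    Jointly fits scale * FD_alpha(envelope) + baseline to the cycle averages
    across all periods by least squares: alpha by bounded 1-D search over
    [0, 1], (scale, baseline) by linear least squares at each alpha.
    Returns (alpha, scale, baseline).
    """
    if envelopes is None:
        envelopes = [ca.envelope for ca in cas]
    if any(e is None for e in envelopes):
        raise ValueError("envelope specs required for the square-wave fit")
    spread = max(float(np.ptp(ca.rates)) for ca in cas)
    mean_lvl = np.mean([ca.rates.mean() for ca in cas])
    if spread < 0.05 * max(mean_lvl, 1e-12):
        raise ValueError("flat responses: alpha is unidentifiable")

    # coarse grid scan to avoid local minima, then refine
    grid = np.linspace(0.0, 1.0, 21)
    sses = [_square_fit_sse(a, cas, envelopes)[0] for a in grid]
    i0 = int(np.argmin(sses))
    lo = grid[max(0, i0 - 1)]
    hi = grid[min(len(grid) - 1, i0 + 1)]
    res = minimize_scalar(
        lambda a: _square_fit_sse(a, cas, envelopes)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    alpha = float(res.x)
    _, (scale, baseline) = _square_fit_sse(alpha, cas, envelopes)
    return alpha, float(scale), float(baseline)


def fit_exponential_timescale(
    ca: CycleAverage,
) -> tuple[float, float]:
    """Exponential decay time constants after the up- and down-step.

    For a square envelope the SD steps up at the start of the cycle and down
    at half-period.  Each half-cycle is fitted with
    r(t) = r_inf + A*exp(-t/tau) by nonlinear least squares; returns
    (tau_up, tau_down) in seconds.  A non-decaying half-cycle returns the
    boundary of the search range (flagged by tau == period).
    """
    n_half = ca.n_bins // 2
    t = (np.arange(n_half) + 0.5) * (ca.period / ca.n_bins)
    taus = []
    for half in (ca.rates[:n_half], ca.rates[n_half : 2 * n_half]):

        def model(t, r_inf, A, log_tau):
            return r_inf + A * np.exp(-t / np.exp(log_tau))

        A0 = half[0] - half[-1]
        try:
            popt, _ = curve_fit(
                model, t, half,
                p0=[half[-1], A0 if A0 != 0 else 1.0, np.log(ca.period / 8)],
                maxfev=5000,
            )
            tau = float(np.exp(popt[2]))
            tau = min(tau, ca.period)  # boundary flag for non-decaying fits
        except RuntimeError:
            tau = ca.period
        taus.append(tau)
    return taus[0], taus[1]
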