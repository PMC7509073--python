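"""Injected-current stimulus generation.

All stimuli are Gaussian white noise sampled independently in each 1 ms bin.
The flat protocol draws every bin from N(mu, (4*mu*sigma)^2); the
variance-modulated protocols replace the constant multiplier sigma by a
periodic envelope f_p(t, sigma) (sine or square), so the per-bin standard
deviation is 4*mu*f_p(t, sigma).  The mean current mu is calibrated per
neuron model so that the baseline (sigma = 1) firing rate is ~10 spk/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

DT_STIM = 1e-3  # stimulus sample width, seconds (1 ms)

__all__ = [
    "DT_STIM",
    "EnvelopeSpec",
    "StimulusTrace",
    "generate_white_noise",
    "envelope_value",
    "generate_modulated_noise",
    "calibrate_mean",
]


@dataclass(frozen=True)
class EnvelopeSpec:
    """Periodic modulation of the noise-SD multiplier.

    kind
        ``"square"``: f = 1 + (sigma-1)*floor(sin(2*pi*t/p)/2 + 1), which takes
        the value sigma on the half-cycle where sin >= 0 and 1 elsewhere.
        ``"sine"``: f = 1 + (sigma-1)*(sin(2*pi*t/p)/2 + 1/2), smoothly
        spanning [1, sigma].
    period_p
        Modulation period in seconds.
    sigma
        Peak SD multiplier, >= 1.
    """

    kind: Literal["sine", "square"]
    period_p: float
    sigma: float

    def __post_init__(self) -> None:
        if self.kind not in ("sine", "square"):
            raise ValueError(f"unknown envelope kind {self.kind!r}")
        if self.period_p <= 0:
            raise ValueError("period_p must be positive")
        if self.sigma < 1:
            raise ValueError("sigma must be >= 1")


@dataclass(frozen=True)
class StimulusTrace:
    """Injected current on the 1 ms stimulus grid.

    ``values[i]`` is the current held constant over bin
    ``[i*dt_sample, (i+1)*dt_sample)`` (zero-order hold on the ODE grid).
    """

    values: np.ndarray
    mean_mu: float
    sd_spec: Union[float, EnvelopeSpec]
    seed: int
    dt_sample: float = DT_STIM

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return len(self.values) * self.dt_sample

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        """Left edge of each bin, seconds."""
        return np.arange(self.n_bins) * self.dt_sample


def _n_bins(duration: float) -> int:
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / DT_STIM))
    if abs(n * DT_STIM - duration) > 1e-9:
        raise ValueError("duration must be a whole number of 1 ms bins")
    return n


def generate_white_noise(
    mu: float, sigma: float, duration: float, seed: int
) -> StimulusTrace:
    """Flat-SD Gaussian white noise: independent draws N(mu, (4*mu*sigma)^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = _n_bins(duration)
    rng = np.random.default_rng(seed)
    values = rng.normal(mu, 4.0 * mu * sigma, size=n)
    return StimulusTrace(values=values, mean_mu=mu, sd_spec=sigma, seed=seed)


def envelope_value(spec: EnvelopeSpec, t: Union[float, np.ndarray]) -> np.ndarray:
    """Evaluate the SD-multiplier envelope f_p(t, sigma) at time(s) t (seconds)."""
    t = np.asarray(t, dtype=np.float64)
    s = np.sin(2.0 * np.pi * t / spec.period_p)
    if spec.kind == "square":
        mod = np.floor(0.5 * s + 1.0)
    else:
        mod = 0.5 * s + 0.5
    return 1.0 + (spec.sigma - 1.0) * mod


def generate_modulated_noise(
    mu: float, spec: EnvelopeSpec, duration: float, seed: int
) -> StimulusTrace:
    """Variance-modulated noise: bin at time t drawn N(mu, (4*mu*f_p(t))^2).

    The envelope is evaluated at the left edge of each 1 ms bin.  ``duration``
    should be an integer multiple of the envelope period (warned otherwise so
    cycle averages are not biased by a partial final cycle).
    """
    n = _n_bins(duration)
    n_cycles = duration / spec.period_p
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        warnings.warn(
            f"duration {duration} s is not a whole number of envelope periods "
            f"({spec.period_p} s); the final cycle is partial",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n) * DT_STIM
    sd = 4.0 * mu * envelope_value(spec, t)
    values = mu + sd * rng.standard_normal(n)
    return StimulusTrace(values=values, mean_mu=mu, sd_spec=spec, seed=seed)


def calibrate_mean(
    model,
    target_rate: float = 10.0,
    calib_duration: float = 100.0,
    tolerance: float = 0.5,
    seed: int = 0,
    mu_bracket: tuple[float, float] = (1e-3, 4.0),
    max_iter: int = 40,
) -> float:
    """Tune the stimulus mean so the baseline (sigma = 1) rate is ~``target_rate``.

    Bisection on mu against the firing rate of a ``calib_duration``-second
    simulation with flat noise, fixed calibration seed.  ``model`` is an
    ``HHParamsGS`` or ``HHParamsAHP`` parameter set (dispatched through
    ``glmadapt.hh.simulate``).  Parameter sets that spike spontaneously at
    mu = 0 are rejected, as are target rates at or below zero (the zero-rate
    boundary is not an interior solution).
    """
    from . import hh  # deferred: avoid import cycle

    if target_rate <= 0:
        raise ValueError("target_rate must be positive; rate 0 is a boundary")
    if hh.spikes_spontaneously(model):
        raise ValueError(
            "parameter set spikes spontaneously at mu=0; rejected from calibration"
        )

    def rate(mu: float) -> float:
        stim = generate_white_noise(mu, 1.0, calib_duration, seed)
        return hh.simulate_spikes(model, stim).rate

    lo, hi = mu_bracket
    r_hi = rate(hi)
    if r_hi < target_rate:
        raise RuntimeError(
            f"firing rate at mu={hi} is {r_hi:.2f} spk/s < target {target_rate}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= tolerance:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
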