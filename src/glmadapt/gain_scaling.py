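"""Gain-scaling quantification via spike-triggered distributions.

A neuron gain-scales when its input-output function rescales the input axis
by the stimulus standard deviation sigma, so that the spike-triggered
distribution of the normalised filtered stimulus s_hat = s/sigma is
invariant to sigma.  The pipeline is:

1. spike-triggered average (STA) of the mean-subtracted stimulus,
2. projection s(t) of the stimulus onto the STA (causal convolution),
3. histograms of s_hat at spike bins and at all bins (bin width 0.1),
4. the gain-scaling score D_sigma = W1(p_1(s_hat|spk), p_sigma(s_hat|spk)),
   the Wasserstein-1 (earth-mover's) distance between the spike-triggered
   distributions at baseline and at sigma.

D close to 0 means the spike-triggered distributions coincide after
normalisation, i.e. the cell scales its gain with sigma.

The STA is normalised so that the projected signal has unit variance after
dividing by sigma, which makes the marginal distribution of s_hat standard
normal for Gaussian stimuli (``norm="projected_variance"``, the default); a
unit-L2-norm convention is available behind ``norm="unit_norm"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hh import SpikeTrain
from .stimulus import StimulusTrace

HIST_BIN_WIDTH = 0.1
HIST_RANGE = (-5.0, 5.0)
MIN_SPIKES = 100

__all__ = [
    "STAFilter",
    "TriggeredDistribution",
    "GainScalingResult",
    "InsufficientSpikesError",
    "compute_sta",
    "project_stimulus",
    "triggered_distributions",
    "wasserstein1",
    "gain_scaling_score",
    "io_function",
    "gain_scaling_analysis",
]


class InsufficientSpikesError(ValueError):
    """Raised when too few spikes are available for a stable estimate."""


@dataclass(frozen=True)
class STAFilter:
    """Normalised spike-triggered average over a causal lag window."""

    values: np.ndarray  # index k = lag of k ms (k = 0 .. window-1)
    window_ms: int
    n_spikes: int
    norm: str = "projected_variance"

    def lags_ms(self) -> np.ndarray:
        return np.arange(self.window_ms, dtype=float)


@dataclass(frozen=True)
class TriggeredDistribution:
    """Histogram over s_hat with fixed bin width 0.1 on [-5, 5].

    Edge bins are open-ended: mass outside the range accumulates in the
    first/last bin so the total mass is exactly 1.
    """

    counts: np.ndarray
    sigma: float
    bin_width: float = HIST_BIN_WIDTH
    lo: float = HIST_RANGE[0]

    @property
    def mass(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram")
        return self.counts / total

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class GainScalingResult:
    """D_sigma scores and input-output curves for one neuron."""

    sigmas: tuple[float, ...]
    D: dict  # sigma -> D_sigma (D at baseline sigma=1 is 0 by construction)
    mean_rate: dict  # sigma -> p(spk)/dt, spk/s
    io_curves: dict  # sigma -> (s_hat_centers, R_hat)
    sta: dict  # sigma -> STAFilter

    @property
    def D2(self) -> float:
        """Headline gain-scaling score, D at sigma = 2."""
        return self.D[2.0]


def _bin_histogram(x: np.ndarray) -> np.ndarray:
    lo, hi = HIST_RANGE
    n_bins = int(round((hi - lo) / HIST_BIN_WIDTH))
    idx = np.floor((x - lo) / HIST_BIN_WIDTH).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)  # open-ended edge bins
    counts = np.zeros(n_bins)
    np.add.at(counts, idx, 1)
    return counts


def compute_sta(
    stim: StimulusTrace,
    spikes: SpikeTrain,
    window_ms: int = 100,
    min_spikes: int = MIN_SPIKES,
    norm: str = "projected_variance",
    sigma: float = 1.0,
) -> STAFilter:
    """Normalised spike-triggered average of the mean-subtracted stimulus.

    The raw STA at lag k is the mean of ``stim[t_spk - k] - mu`` over spikes
    (spikes in the first ``window_ms`` bins are excluded so every segment is
    complete).  Normalisation:

    - ``"projected_variance"``: scaled so the projected signal divided by
      ``sigma`` has unit variance on this trace, making the marginal of
      s_hat standard normal for white Gaussian input;
    - ``"unit_norm"``: unit L2 norm.
    """
    x = stim.values - stim.mean_mu
    counts = spikes.counts
    n = len(x)
    if len(counts) != n:
        raise ValueError("stimulus and spike train lengths differ")
    spike_bins = np.flatnonzero(counts)
    spike_bins = spike_bins[spike_bins >= window_ms]
    weights = counts[spike_bins].astype(float)
    n_spk = int(weights.sum())
    if n_spk < min_spikes:
        raise InsufficientSpikesError(
            f"{n_spk} spikes < required minimum {min_spikes}"
        )
    sta = np.zeros(window_ms)
    # mean over spikes of the preceding stimulus segment; lag 0 = spike bin
    for k in range(window_ms):
        sta[k] = np.average(x[spike_bins - k], weights=weights)
    if norm == "unit_norm":
        sta = sta / np.linalg.norm(sta)
    elif norm == "projected_variance":
        s = _causal_convolve(x, sta)
        sd = np.std(s / sigma)
        if sd == 0:
            raise ValueError("projected signal has zero variance")
        sta = sta / sd
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return STAFilter(values=sta, window_ms=window_ms, n_spikes=n_spk, norm=norm)


def _causal_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(x, kernel)[: len(x)]


def project_stimulus(
    stim: StimulusTrace, sta: STAFilter, mu: float | None = None
) -> np.ndarray:
    """Causal convolution s(t) = sum_k STA(k) * (x(t-k) - mu)."""
    if mu is None:
        mu = stim.mean_mu
    return _causal_convolve(stim.values - mu, sta.values)


def triggered_distributions(
    s: np.ndarray, spikes: SpikeTrain, sigma: float
) -> tuple[TriggeredDistribution, TriggeredDistribution]:
    """Histograms of s_hat = s/sigma at spike bins and at all bins."""
    counts = spikes.counts
    if len(counts) != len(s):
        raise ValueError("projected signal and spike train lengths differ")
    if counts.sum() == 0:
        raise InsufficientSpikesError("empty spike train")
    s_hat = s / sigma
    spk_hist = np.zeros(int(round((HIST_RANGE[1] - HIST_RANGE[0]) / HIST_BIN_WIDTH)))
    idx = np.floor((s_hat - HIST_RANGE[0]) / HIST_BIN_WIDTH).astype(np.int64)
    np.clip(idx, 0, len(spk_hist) - 1, out=idx)
    np.add.at(spk_hist, idx, counts.astype(float))
    prior_hist = _bin_histogram(s_hat)
    return (
        TriggeredDistribution(counts=spk_hist, sigma=sigma),
        TriggeredDistribution(counts=prior_hist, sigma=sigma),
    )


def wasserstein1(hA: TriggeredDistribution, hB: TriggeredDistribution) -> float:
    """Wasserstein-1 distance between two binned distributions.

    In one dimension the optimal-transport cost has the closed form
    sum_bins |CDF_A - CDF_B| * bin_width.
    """
    if hA.n_bins != hB.n_bins or hA.bin_width != hB.bin_width or hA.lo != hB.lo:
        raise ValueError("histograms must share the same bin grid")
    a, b = hA.mass, hB.mass
    if not (np.isclose(a.sum(), 1.0) and np.isclose(b.sum(), 1.0)):
        raise ValueError("inputs must be normalised distributions")
    cdf_diff = np.cumsum(a - b)
    return float(np.abs(cdf_diff).sum() * hA.bin_width)


def gain_scaling_score(
    baseline: TriggeredDistribution, at_sigma: TriggeredDistribution
) -> float:
    """D_sigma = W1 between spike-triggered distributions at sigma=1 and sigma."""
    return wasserstein1(baseline, at_sigma)


def io_function(
    s: np.ndarray,
    spikes: SpikeTrain,
    sigma: float,
    dt: float = 1e-3,
    min_prior_count: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Input-output curve R_hat(s_hat) = p(s_hat|spk) p(spk) / (p(s_hat) dt).

    Returned only over bins where the prior histogram has at least
    ``min_prior_count`` samples (variance control of the ratio estimator).
    """
    spk_h, prior_h = triggered_distributions(s, spikes, sigma)
    p_spk = spikes.counts.sum() / len(s)
    support = prior_h.counts >= min_prior_count
    centers = prior_h.bin_centers()[support]
    ratio = (spk_h.mass[support] / prior_h.mass[support]) * p_spk / dt
    return centers, ratio


def gain_scaling_analysis(
    condition_data: dict,
    window_ms: int = 100,
    norm: str = "projected_variance",
    min_spikes: int = MIN_SPIKES,
) -> GainScalingResult:
    """Full analysis across stimulus SDs.

    ``condition_data`` maps sigma -> (StimulusTrace, SpikeTrain); must include
    the baseline sigma = 1.0.  An STA is computed per sigma, the stimulus is
    projected, and D_sigma compares each sigma's spike-triggered distribution
    of s_hat with baseline.
    """
    if 1.0 not in condition_data:
        raise ValueError("baseline condition sigma=1.0 is required")
    sigmas = tuple(sorted(condition_data))
    stas, spk_dists, io_curves, mean_rate = {}, {}, {}, {}
    for sigma in sigmas:
        stim, spikes = condition_data[sigma]
        sta = compute_sta(stim, spikes, window_ms, min_spikes, norm, sigma)
        s = project_stimulus(stim, sta)
        spk_h, prior_h = triggered_distributions(s, spikes, sigma)
        stas[sigma] = sta
        spk_dists[sigma] = spk_h
        io_curves[sigma] = io_function(s, spikes, sigma)
        mean_rate[sigma] = spikes.rate
    D = {sigma: wasserstein1(spk_dists[1.0], spk_dists[sigma]) for sigma in sigmas}
    return GainScalingResult(
        sigmas=sigmas, D=D, mean_rate=mean_rate, io_curves=io_curves, sta=stas
    )
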