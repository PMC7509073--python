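"""Raised-cosine and boxcar basis sets for GLM filters.

The stimulus filter uses 15 log-spaced raised cosines with peaks between 0
and 100 ms.  The spike-history filter prepends 5 boxcars of width 2 ms
(covering the first 10 ms, the absolute refractory period) to N raised
cosines: N = 15 with peaks 10-150 ms for the gain-scaling fits, N = 25 with
peaks 10 ms - 16 s for the fractional-differentiation fits.

A raised cosine with centre phi_j and width parameter a is

    g_j(t) = cos((log(t + c) - phi_j) / a) / 2 + 1/2

on |log(t + c) - phi_j| <= a*pi and zero outside, with t in seconds.  The
phi_j are evenly spaced between log(T0/1000 + c) and log(Tend/1000 + c) and
a = 2*(phi_2 - phi_1)/pi, so adjacent cosines overlap smoothly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

DT_MS = 1.0

__all__ = ["BasisSet", "make_stimulus_basis", "make_history_basis", "raised_cosines"]


@dataclass(frozen=True)
class BasisSet:
    """Filter basis sampled on the 1 ms lag grid.

    ``functions`` has shape (n_basis, n_lags); row j is basis function j
    evaluated at the lags in ``lags_ms``.  For history bases the first
    ``n_boxcars`` rows are the refractory boxcars and ``peak_times_ms``
    holds the cosine peak lags (used to label nested fits by T_hist).
    """

    kind: Literal["stimulus", "history"]
    functions: np.ndarray
    lags_ms: np.ndarray
    peak_times_ms: np.ndarray  # peak lag per raised cosine
    n_boxcars: int = 0

    @property
    def n_basis(self) -> int:
        return self.functions.shape[0]

    @property
    def n_cosines(self) -> int:
        return self.n_basis - self.n_boxcars

    @property
    def n_lags(self) -> int:
        return self.functions.shape[1]

    def truncate_cosines(self, i: int) -> "BasisSet":
        """Keep the boxcars and only the first ``i`` raised cosines."""
        if not 0 <= i <= self.n_cosines:
            raise ValueError(f"i must be in [0, {self.n_cosines}]")
        keep = self.n_boxcars + i
        funcs = self.functions[:keep]
        if i > 0:
            n_lags = int(np.flatnonzero(np.abs(funcs).sum(axis=0) > 0)[-1]) + 1
        else:
            n_lags = self.n_boxcars * 2
        return BasisSet(
            kind=self.kind,
            functions=funcs[:, :n_lags],
            lags_ms=self.lags_ms[:n_lags],
            peak_times_ms=self.peak_times_ms[:i],
            n_boxcars=self.n_boxcars,
        )

    def t_hist_ms(self, i: int) -> float:
        """History length label for a fit with i cosines: the peak time of
        the i-th cosine, or the end of the boxcar section for i = 0."""
        if i == 0:
            return self.n_boxcars * 2.0
        return float(self.peak_times_ms[i - 1])


def raised_cosines(
    n: int, t0_ms: float, tend_ms: float, c: float, lags_ms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate n log-spaced raised cosines on ``lags_ms`` (times in seconds
    internally).  Returns (functions, peak_times_ms)."""
    t = np.asarray(lags_ms, dtype=float) / 1000.0
    phi = np.linspace(np.log(t0_ms / 1000.0 + c), np.log(tend_ms / 1000.0 + c), n)
    a = 2.0 * (phi[1] - phi[0]) / np.pi
    arg = (np.log(t + c)[None, :] - phi[:, None]) / a
    funcs = np.where(np.abs(arg) <= np.pi, 0.5 * np.cos(arg) + 0.5, 0.0)
    peaks_ms = (np.exp(phi) - c) * 1000.0
    return funcs, peaks_ms


def make_stimulus_basis() -> BasisSet:
    """15 raised cosines with peaks from 0 to 100 ms, c = 0.02."""
    c = 0.02
    n, t0, tend = 15, 0.0, 100.0
    # support of the last cosine sets the lag-grid length
    phi = np.linspace(np.log(t0 / 1000 + c), np.log(tend / 1000 + c), n)
    a = 2.0 * (phi[1] - phi[0]) / np.pi
    t_max_ms = (np.exp(phi[-1] + a * np.pi) - c) * 1000.0
    lags = np.arange(int(np.ceil(t_max_ms)) + 1, dtype=float)
    funcs, peaks = raised_cosines(n, t0, tend, c, lags)
    return BasisSet(
        kind="stimulus", functions=funcs, lags_ms=lags, peak_times_ms=peaks
    )


def make_history_basis(variant: Literal["gain_scaling", "fracdiff"]) -> BasisSet:
    """5 refractory boxcars (0-10 ms) + N raised cosines, c = 0.05.

    gain_scaling: N = 15, peaks 10-150 ms; fracdiff: N = 25, peaks 10 ms-16 s.
    History lags start at 1 ms (strictly causal: bin t sees spikes in bins
    < t), so lag k on this grid means "k ms before the current bin" and
    boxcar j covers lags (2j-2, 2j].
    """
    c = 0.05
    if variant == "gain_scaling":
        n, t0, tend = 15, 10.0, 150.0
    elif variant == "fracdiff":
        n, t0, tend = 25, 10.0, 16000.0
    else:
        raise ValueError(f"unknown history variant {variant!r}")
    phi = np.linspace(np.log(t0 / 1000 + c), np.log(tend / 1000 + c), n)
    a = 2.0 * (phi[1] - phi[0]) / np.pi
    t_max_ms = (np.exp(phi[-1] + a * np.pi) - c) * 1000.0
    lags = np.arange(1, int(np.ceil(t_max_ms)) + 1, dtype=float)
    cos_funcs, peaks = raised_cosines(n, t0, tend, c, lags)
    box_funcs = np.zeros((5, len(lags)))
    for j in range(5):
        box_funcs[j, 2 * j : 2 * j + 2] = 1.0
    funcs = np.vstack([box_funcs, cos_funcs])
    return BasisSet(
        kind="history", functions=funcs, lags_ms=lags, peak_times_ms=peaks,
        n_boxcars=5,
    )
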