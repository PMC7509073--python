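"""Single-compartment Hodgkin-Huxley simulators and spike detection.

Two model variants are implemented:

``HHParamsGS``
    A cortical-neuron model with Mainen-style kinetics whose total sodium and
    potassium conductances (G_Na, G_K, in pS/um^2) are varied to control gain
    scaling.  The potassium current is first order in the activation gate n
    (a Kv-style channel), and the printed rate constants are in s^-1 with V in
    mV (converted to ms^-1 internally).  The leak of 0.4 pS/um^2 with
    C = 1 uF/cm^2 gives a 25 ms resting membrane time constant
    (1 pS/um^2 = 0.1 mS/cm^2).

``HHParamsAHP``
    The classical squid-axon HH model (n^4 potassium kinetics, rates in ms^-1)
    augmented with three afterhyperpolarization (AHP) conductances whose
    activations a_i decay exponentially with time constants of 0.3, 1 and 6 s
    and are incremented by 1 at each spike, producing spike-frequency
    adaptation over multiple timescales.

Both are integrated with a fixed-step fourth-order Runge-Kutta scheme at
dt = 0.01 ms; the injected current is held constant over each 1 ms stimulus
bin.  Spikes are upward crossings of -10 mV separated by at least 2 ms.  The
AHP model detects spikes online during integration because the increments
feed back into the dynamics; the gain-scaling model can be detected offline
from the voltage trace with the identical crossing rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .stimulus import StimulusTrace

DT_ODE_MS = 0.01  # RK4 step, ms
SPIKE_THRESHOLD_MV = -10.0
REFRACTORY_MS = 2.0
PS_UM2_TO_MS_CM2 = 0.1  # 1 pS/um^2 = 0.1 mS/cm^2

__all__ = [
    "HHParamsGS",
    "HHParamsAHP",
    "VoltageTrace",
    "SpikeTrain",
    "simulate",
    "simulate_hh_gs",
    "simulate_hh_ahp",
    "simulate_spikes",
    "detect_spikes",
    "spikes_spontaneously",
    "resting_state",
]


@dataclass(frozen=True)
class HHParamsGS:
    """Gain-scaling HH model parameters (conductances in pS/um^2)."""

    G_Na: float = 1000.0
    G_K: float = 1000.0
    G_L: float = 0.4
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -70.0
    C: float = 1.0  # uF/cm^2

    @property
    def ratio(self) -> float:
        return self.G_Na / self.G_K

    @property
    def membrane_tau_ms(self) -> float:
        """Resting time constant C / G_L (unit-conversion self-check: 25 ms)."""
        return self.C / (self.G_L * PS_UM2_TO_MS_CM2)


@dataclass(frozen=True)
class HHParamsAHP:
    """Squid-axon HH with three AHP currents (conductances in mS/cm^2)."""

    G_Na: float = 120.0
    G_K: float = 36.0
    G_L: float = 0.3
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.4
    C: float = 1.0
    G_AHP: tuple[float, float, float] = (0.05 * 0.3, 0.006 * 0.3, 0.004 * 0.3)
    E_AHP: float = -100.0
    tau_AHP_s: tuple[float, float, float] = (0.3, 1.0, 6.0)

    def __post_init__(self) -> None:
        if len(self.G_AHP) != 3 or len(self.tau_AHP_s) != 3:
            raise ValueError("exactly three AHP channels required")
        if not (self.tau_AHP_s[0] < self.tau_AHP_s[1] < self.tau_AHP_s[2]):
            raise ValueError("AHP time constants must be strictly increasing")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s), strictly increasing, with 1 ms binned counts.

    Trains detected from HH voltage traces additionally satisfy the 2 ms
    refractory rule (see :func:`detect_spikes`); GLM-simulated trains need
    not, so that rule is checked by :meth:`respects_refractory`, not here.
    """

    spike_times: np.ndarray
    duration: float
    dt_bin: float = 1e-3

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=np.float64)
        object.__setattr__(self, "spike_times", st)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def respects_refractory(self, refractory_ms: float = REFRACTORY_MS) -> bool:
        st = self.spike_times
        return bool(st.size < 2 or np.all(np.diff(st) >= refractory_ms * 1e-3 - 1e-12))

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def rate(self) -> float:
        """Mean firing rate in spk/s."""
        return self.n_spikes / self.duration

    @cached_property
    def counts(self) -> np.ndarray:
        """Spike counts per 1 ms bin (int64, length duration/dt_bin)."""
        n = int(round(self.duration / self.dt_bin))
        idx = np.minimum((self.spike_times / self.dt_bin).astype(np.int64), n - 1)
        counts = np.zeros(n, dtype=np.int64)
        np.add.at(counts, idx, 1)
        return counts


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane state on the ODE grid (dt = 0.01 ms)."""

    V: np.ndarray
    gates: np.ndarray  # (n_steps, 3): n, m, h
    duration: float
    dt_ms: float = DT_ODE_MS
    ahp: np.ndarray | None = None  # (n_steps, 3) AHP activations, AHP model only
    spike_times: np.ndarray | None = None  # filled when detected online

    def times(self) -> np.ndarray:
        return np.arange(len(self.V)) * self.dt_ms * 1e-3


# ---------------------------------------------------------------------------
# Rate functions (vectorised NumPy mirrors of the numba kernels, used for
# fixed points and tests)


def _lexp(x, k):
    """x / (1 - exp(-x/k)), continuous at x = 0 where the limit is k."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    out = np.where(small, k + x / 2.0, safe / (1.0 - np.exp(-safe / k)))
    return out


def gs_rates(V):
    """Gain-scaling model gating rates in ms^-1 (printed constants are s^-1)."""
    a_n = 20.0 * _lexp(V - 20.0, 9.0) * 1e-3
    b_n = 2.0 * _lexp(-(V - 20.0), 9.0) * 1e-3
    a_m = 182.0 * _lexp(V + 35.0, 9.0) * 1e-3
    b_m = 124.0 * _lexp(-(V + 35.0), 9.0) * 1e-3
    a_h = 24.0 * _lexp(V + 50.0, 5.0) * 1e-3
    b_h = 9.1 * _lexp(-(V + 75.0), 5.0) * 1e-3
    return a_n, b_n, a_m, b_m, a_h, b_h


def gs_steady_state(V):
    """(n_inf, m_inf, h_inf) for the gain-scaling model."""
    a_n, b_n, a_m, b_m, a_h, b_h = gs_rates(V)
    n_inf = a_n / (a_n + b_n)
    m_inf = a_m / (a_m + b_m)
    h_inf = 1.0 / (1.0 + np.exp((V + 65.0) / 6.2))
    return n_inf, m_inf, h_inf


def ahp_rates(V):
    """Classical HH gating rates in ms^-1."""
    a_n = 0.01 * _lexp(V + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    a_m = 0.1 * _lexp(V + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-0.1 * (V + 35.0)))
    return a_n, b_n, a_m, b_m, a_h, b_h


def ahp_steady_state(V):
    a_n, b_n, a_m, b_m, a_h, b_h = ahp_rates(V)
    return a_n / (a_n + b_n), a_m / (a_m + b_m), a_h / (a_h + b_h)


def _gs_ss_current(V: float, p: HHParamsGS) -> float:
    n_inf, m_inf, h_inf = gs_steady_state(V)
    g_na = p.G_Na * PS_UM2_TO_MS_CM2
    g_k = p.G_K * PS_UM2_TO_MS_CM2
    g_l = p.G_L * PS_UM2_TO_MS_CM2
    return float(
        -g_na * m_inf**3 * h_inf * (V - p.E_Na)
        - g_k * n_inf * (V - p.E_K)
        - g_l * (V - p.E_L)
    )


def _ahp_ss_current(V: float, p: HHParamsAHP) -> float:
    n_inf, m_inf, h_inf = ahp_steady_state(V)
    return float(
        -p.G_Na * m_inf**3 * h_inf * (V - p.E_Na)
        - p.G_K * n_inf**4 * (V - p.E_K)
        - p.G_L * (V - p.E_L)
    )


def resting_state(params) -> np.ndarray:
    """I=0 fixed point (V, n, m, h[, a1..a3]) found by 1-D root bracketing."""
    if isinstance(params, HHParamsGS):
        f = lambda V: _gs_ss_current(V, params)
        ss = gs_steady_state
        n_extra = 0
    elif isinstance(params, HHParamsAHP):
        f = lambda V: _ahp_ss_current(V, params)
        ss = ahp_steady_state
        n_extra = 3
    else:
        raise TypeError(f"unknown parameter type {type(params)}")
    # bracket the rest point in the subthreshold range
    v_rest = brentq(f, -90.0, -35.0, xtol=1e-10)
    n_inf, m_inf, h_inf = ss(v_rest)
    state = [v_rest, float(n_inf), float(m_inf), float(h_inf)]
    state += [0.0] * n_extra
    return np.array(state)


# ---------------------------------------------------------------------------
# Numba kernels


@njit(cache=False, fastmath=False)
def _nb_lexp(x, k):
    if abs(x) < 1e-9:
        return k + 0.5 * x
    return x / (1.0 - np.exp(-x / k))


@njit(cache=False)
def _gs_derivs(V, n, m, h, I, g_na, g_k, g_l, e_na, e_k, e_l, c):
    a_n = 0.020 * _nb_lexp(V - 20.0, 9.0)
    b_n = 0.002 * _nb_lexp(-(V - 20.0), 9.0)
    a_m = 0.182 * _nb_lexp(V + 35.0, 9.0)
    b_m = 0.124 * _nb_lexp(-(V + 35.0), 9.0)
    a_h = 0.024 * _nb_lexp(V + 50.0, 5.0)
    b_h = 0.0091 * _nb_lexp(-(V + 75.0), 5.0)
    n_inf = a_n / (a_n + b_n)
    m_inf = a_m / (a_m + b_m)
    h_inf = 1.0 / (1.0 + np.exp((V + 65.0) / 6.2))
    dV = (
        I
        - g_na * m * m * m * h * (V - e_na)
        - g_k * n * (V - e_k)
        - g_l * (V - e_l)
    ) / c
    dn = (n_inf - n) * (a_n + b_n)
    dm = (m_inf - m) * (a_m + b_m)
    dh = (h_inf - h) * (a_h + b_h)
    return dV, dn, dm, dh


@njit(cache=False)
def _gs_kernel(
    stim, steps_per_bin, dt, state0, g_na, g_k, g_l, e_na, e_k, e_l, c,
    settle_steps, settle_I, record, v_out, g_out, spike_buf,
):
    V, n, m, h = state0[0], state0[1], state0[2], state0[3]
    # settle at constant current, not recorded
    for i in range(settle_steps):
        d1 = _gs_derivs(V, n, m, h, settle_I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d2 = _gs_derivs(V + 0.5 * dt * d1[0], n + 0.5 * dt * d1[1],
                        m + 0.5 * dt * d1[2], h + 0.5 * dt * d1[3],
                        settle_I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d3 = _gs_derivs(V + 0.5 * dt * d2[0], n + 0.5 * dt * d2[1],
                        m + 0.5 * dt * d2[2], h + 0.5 * dt * d2[3],
                        settle_I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d4 = _gs_derivs(V + dt * d3[0], n + dt * d3[1],
                        m + dt * d3[2], h + dt * d3[3],
                        settle_I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        V += dt / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        n += dt / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        m += dt / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        h += dt / 6.0 * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])

    n_steps = len(stim) * steps_per_bin
    n_spk = 0
    last_spike_ms = -1e30
    v_prev = V
    for i in range(n_steps):
        I = stim[i // steps_per_bin]
        d1 = _gs_derivs(V, n, m, h, I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d2 = _gs_derivs(V + 0.5 * dt * d1[0], n + 0.5 * dt * d1[1],
                        m + 0.5 * dt * d1[2], h + 0.5 * dt * d1[3],
                        I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d3 = _gs_derivs(V + 0.5 * dt * d2[0], n + 0.5 * dt * d2[1],
                        m + 0.5 * dt * d2[2], h + 0.5 * dt * d2[3],
                        I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        d4 = _gs_derivs(V + dt * d3[0], n + dt * d3[1],
                        m + dt * d3[2], h + dt * d3[3],
                        I, g_na, g_k, g_l, e_na, e_k, e_l, c)
        V += dt / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        n += dt / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        m += dt / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        h += dt / 6.0 * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])
        if not (abs(V) <= 500.0):  # catches divergence and NaN
            return -1, i
        if record:
            v_out[i] = V
            g_out[i, 0] = n
            g_out[i, 1] = m
            g_out[i, 2] = h
        t_ms = (i + 1) * dt
        if v_prev < -10.0 and V >= -10.0 and t_ms - last_spike_ms >= 2.0:
            if n_spk < len(spike_buf):
                spike_buf[n_spk] = t_ms
            n_spk += 1
            last_spike_ms = t_ms
        v_prev = V
    return n_spk, n_steps


@njit(cache=False)
def _ahp_derivs(V, n, m, h, a1, a2, a3, I, p):
    # p: g_na, g_k, g_l, e_na, e_k, e_l, c, g1, g2, g3, e_ahp, tau1, tau2, tau3
    a_n = 0.01 * _nb_lexp(V + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    a_m = 0.1 * _nb_lexp(V + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-0.1 * (V + 35.0)))
    dV = (
        I
        - p[0] * m * m * m * h * (V - p[3])
        - p[1] * n * n * n * n * (V - p[4])
        - p[2] * (V - p[5])
        - (p[7] * a1 + p[8] * a2 + p[9] * a3) * (V - p[10])
    ) / p[6]
    dn = a_n * (1.0 - n) - b_n * n
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    da1 = -a1 / p[11]
    da2 = -a2 / p[12]
    da3 = -a3 / p[13]
    return dV, dn, dm, dh, da1, da2, da3


@njit(cache=False)
def _ahp_kernel(
    stim, steps_per_bin, dt, state0, p,
    settle_steps, settle_I, record, v_out, g_out, a_out, spike_buf,
):
    V, n, m, h = state0[0], state0[1], state0[2], state0[3]
    a1, a2, a3 = state0[4], state0[5], state0[6]
    n_steps = len(stim) * steps_per_bin
    n_spk = 0
    last_spike_ms = -1e30
    v_prev = V
    total = settle_steps + n_steps
    for j in range(total):
        if j < settle_steps:
            I = settle_I
        else:
            I = stim[(j - settle_steps) // steps_per_bin]
        d1 = _ahp_derivs(V, n, m, h, a1, a2, a3, I, p)
        d2 = _ahp_derivs(V + 0.5 * dt * d1[0], n + 0.5 * dt * d1[1],
                         m + 0.5 * dt * d1[2], h + 0.5 * dt * d1[3],
                         a1 + 0.5 * dt * d1[4], a2 + 0.5 * dt * d1[5],
                         a3 + 0.5 * dt * d1[6], I, p)
        d3 = _ahp_derivs(V + 0.5 * dt * d2[0], n + 0.5 * dt * d2[1],
                         m + 0.5 * dt * d2[2], h + 0.5 * dt * d2[3],
                         a1 + 0.5 * dt * d2[4], a2 + 0.5 * dt * d2[5],
                         a3 + 0.5 * dt * d2[6], I, p)
        d4 = _ahp_derivs(V + dt * d3[0], n + dt * d3[1],
                         m + dt * d3[2], h + dt * d3[3],
                         a1 + dt * d3[4], a2 + dt * d3[5],
                         a3 + dt * d3[6], I, p)
        V += dt / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        n += dt / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        m += dt / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        h += dt / 6.0 * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])
        a1 += dt / 6.0 * (d1[4] + 2 * d2[4] + 2 * d3[4] + d4[4])
        a2 += dt / 6.0 * (d1[5] + 2 * d2[5] + 2 * d3[5] + d4[5])
        a3 += dt / 6.0 * (d1[6] + 2 * d2[6] + 2 * d3[6] + d4[6])
        if not (abs(V) <= 500.0):  # catches divergence and NaN
            return -1, j
        # online spike detection: AHP increments feed back into the dynamics
        if j >= settle_steps:
            i = j - settle_steps
            t_ms = (i + 1) * dt
            if v_prev < -10.0 and V >= -10.0 and t_ms - last_spike_ms >= 2.0:
                a1 += 1.0
                a2 += 1.0
                a3 += 1.0
                if n_spk < len(spike_buf):
                    spike_buf[n_spk] = t_ms
                n_spk += 1
                last_spike_ms = t_ms
        else:
            # spikes during settle still increment the AHP states
            t_ms = (j + 1) * dt - settle_steps * dt
            if v_prev < -10.0 and V >= -10.0:
                a1 += 1.0
                a2 += 1.0
                a3 += 1.0
        if record and j >= settle_steps:
            i = j - settle_steps
            v_out[i] = V
            g_out[i, 0] = n
            g_out[i, 1] = m
            g_out[i, 2] = h
            a_out[i, 0] = a1
            a_out[i, 1] = a2
            a_out[i, 2] = a3
        v_prev = V
    return n_spk, total


# ---------------------------------------------------------------------------
# Public simulation API


class IntegrationError(RuntimeError):
    """Raised when the membrane potential diverges (|V| > 500 mV)."""


def _steps_per_bin(stim: StimulusTrace) -> int:
    spb = int(round(stim.dt_sample * 1e3 / DT_ODE_MS))
    if abs(spb * DT_ODE_MS - stim.dt_sample * 1e3) > 1e-9:
        raise ValueError("stimulus bin width must be a multiple of the ODE step")
    return spb


def _run_gs(params, stim, record, settle_s, dt_ms=DT_ODE_MS):
    state0 = resting_state(params)
    spb = int(round(stim.dt_sample * 1e3 / dt_ms))
    n_steps = stim.n_bins * spb
    if record:
        v_out = np.empty(n_steps)
        g_out = np.empty((n_steps, 3))
    else:
        v_out = np.empty(0)
        g_out = np.empty((0, 3))
    spike_buf = np.empty(int(stim.duration * 1000 / 2) + 16)
    n_spk, n_done = _gs_kernel(
        stim.values, spb, dt_ms, state0,
        params.G_Na * PS_UM2_TO_MS_CM2, params.G_K * PS_UM2_TO_MS_CM2,
        params.G_L * PS_UM2_TO_MS_CM2,
        params.E_Na, params.E_K, params.E_L, params.C,
        int(round(settle_s * 1e3 / dt_ms)), stim.mean_mu,
        record, v_out, g_out, spike_buf,
    )
    if n_spk < 0:
        raise IntegrationError(
            f"|V| exceeded 500 mV at t = {n_done * dt_ms * 1e-3:.4f} s"
        )
    spikes = spike_buf[:n_spk] * 1e-3
    return v_out, g_out, None, spikes


def _run_ahp(params, stim, record, settle_s, dt_ms=DT_ODE_MS):
    state0 = resting_state(params)
    spb = int(round(stim.dt_sample * 1e3 / dt_ms))
    n_steps = stim.n_bins * spb
    if record:
        v_out = np.empty(n_steps)
        g_out = np.empty((n_steps, 3))
        a_out = np.empty((n_steps, 3))
    else:
        v_out = np.empty(0)
        g_out = np.empty((0, 3))
        a_out = np.empty((0, 3))
    p = np.array([
        params.G_Na, params.G_K, params.G_L,
        params.E_Na, params.E_K, params.E_L, params.C,
        params.G_AHP[0], params.G_AHP[1], params.G_AHP[2], params.E_AHP,
        params.tau_AHP_s[0] * 1e3, params.tau_AHP_s[1] * 1e3,
        params.tau_AHP_s[2] * 1e3,
    ])
    spike_buf = np.empty(int(stim.duration * 1000 / 2) + 16)
    n_spk, n_done = _ahp_kernel(
        stim.values, spb, dt_ms, state0, p,
        int(round(settle_s * 1e3 / dt_ms)), stim.mean_mu,
        record, v_out, g_out, a_out, spike_buf,
    )
    if n_spk < 0:
        raise IntegrationError(
            f"|V| exceeded 500 mV at t = {n_done * dt_ms * 1e-3:.4f} s"
        )
    spikes = spike_buf[:n_spk] * 1e-3
    return v_out, g_out, a_out, spikes


def simulate_hh_gs(
    params: HHParamsGS, stim: StimulusTrace, settle_s: float = 1.0,
    dt_ms: float = DT_ODE_MS,
) -> VoltageTrace:
    """Integrate the gain-scaling model, returning the full voltage trace.

    The state is initialised at the I=0 resting fixed point and settled for
    ``settle_s`` seconds at the constant mean current before the stimulus
    starts (the settle segment is not recorded).
    """
    if stim.duration <= 0:
        raise ValueError("stimulus duration must be positive")
    v, g, _, spikes = _run_gs(params, stim, True, settle_s, dt_ms)
    return VoltageTrace(V=v, gates=g, duration=stim.duration, dt_ms=dt_ms,
                        spike_times=spikes)


def simulate_hh_ahp(
    params: HHParamsAHP, stim: StimulusTrace, settle_s: float = 1.0,
    dt_ms: float = DT_ODE_MS,
) -> VoltageTrace:
    """Integrate the AHP model with online spike detection; returns the trace."""
    if stim.duration <= 0:
        raise ValueError("stimulus duration must be positive")
    v, g, a, spikes = _run_ahp(params, stim, True, settle_s, dt_ms)
    return VoltageTrace(V=v, gates=g, ahp=a, duration=stim.duration, dt_ms=dt_ms,
                        spike_times=spikes)


def simulate_spikes(params, stim: StimulusTrace, settle_s: float = 1.0) -> SpikeTrain:
    """Memory-light simulation returning only the detected spike train.

    Uses the same integrator and crossing rule as the trace-recording paths
    but does not store the voltage, so long (hundreds of seconds) production
    runs stay cheap.
    """
    if isinstance(params, HHParamsGS):
        _, _, _, spikes = _run_gs(params, stim, False, settle_s)
    elif isinstance(params, HHParamsAHP):
        _, _, _, spikes = _run_ahp(params, stim, False, settle_s)
    else:
        raise TypeError(f"unknown parameter type {type(params)}")
    return SpikeTrain(spike_times=spikes, duration=stim.duration)


def simulate(params, stim: StimulusTrace, settle_s: float = 1.0) -> VoltageTrace:
    """Dispatch to the appropriate integrator based on the parameter type."""
    if isinstance(params, HHParamsGS):
        return simulate_hh_gs(params, stim, settle_s)
    if isinstance(params, HHParamsAHP):
        return simulate_hh_ahp(params, stim, settle_s)
    raise TypeError(f"unknown parameter type {type(params)}")


def detect_spikes(v: VoltageTrace) -> SpikeTrain:
    """Upward crossings of -10 mV separated by >= 2 ms.

    A spike is the first sample with V >= -10 mV following a sample with
    V < -10 mV; crossings within 2 ms of the previous accepted spike are
    discarded.  Matches the online rule used inside the AHP integrator.
    """
    V = v.V
    above = V >= SPIKE_THRESHOLD_MV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times_ms = crossings * v.dt_ms
    accepted = []
    last = -np.inf
    for t in times_ms:
        if t - last >= REFRACTORY_MS:
            accepted.append(t)
            last = t
    return SpikeTrain(spike_times=np.asarray(accepted) * 1e-3, duration=v.duration)


def spikes_spontaneously(params, probe_duration: float = 3.0) -> bool:
    """Check whether the model fires with zero input current (mu = 0).

    Simulates from a generic subthreshold initial condition with I = 0 and
    reports whether any spike occurs.  Parameter sets that spike at mu = 0
    are excluded from the gain-scaling conductance grid.
    """
    stim = StimulusTrace(
        values=np.zeros(int(probe_duration * 1000)), mean_mu=0.0,
        sd_spec=1.0, seed=0,
    )
    # start away from the fixed point so an unstable rest state reveals itself
    state0 = resting_state(params)
    state0[0] += 2.0
    if isinstance(params, HHParamsGS):
        spb = _steps_per_bin(stim)
        spike_buf = np.empty(4096)
        n_spk, _ = _gs_kernel(
            stim.values, spb, DT_ODE_MS, state0,
            params.G_Na * PS_UM2_TO_MS_CM2, params.G_K * PS_UM2_TO_MS_CM2,
            params.G_L * PS_UM2_TO_MS_CM2,
            params.E_Na, params.E_K, params.E_L, params.C,
            0, 0.0, False, np.empty(0), np.empty((0, 3)), spike_buf,
        )
    elif isinstance(params, HHParamsAHP):
        spb = _steps_per_bin(stim)
        p = np.array([
            params.G_Na, params.G_K, params.G_L,
            params.E_Na, params.E_K, params.E_L, params.C,
            params.G_AHP[0], params.G_AHP[1], params.G_AHP[2], params.E_AHP,
            params.tau_AHP_s[0] * 1e3, params.tau_AHP_s[1] * 1e3,
            params.tau_AHP_s[2] * 1e3,
        ])
        spike_buf = np.empty(4096)
        n_spk, _ = _ahp_kernel(
            stim.values, spb, DT_ODE_MS, state0, p, 0, 0.0,
            False, np.empty(0), np.empty((0, 3)), np.empty((0, 3)), spike_buf,
        )
    else:
        raise TypeError(f"unknown parameter type {type(params)}")
    return n_spk > 0
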