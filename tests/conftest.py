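"""Shared fixtures: small simulations and a known ground-truth GLM.

All data is generated at test time; session scope keeps the expensive
simulator and fit calls to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from glmadapt import basis, glm, hh, stimulus
from glmadapt.glm import DT, _causal_cols, _sim_kernel


@pytest.fixture(scope="session")
def gs_params():
    return hh.HHParamsGS()


@pytest.fixture(scope="session")
def ahp_params():
    return hh.HHParamsAHP()


# operating points giving ~10 spk/s at sigma = 1 (checked by test_hh's
# calibration-bracket test; full bisection calibration runs in the
# acceptance suite)
GS_MU = 0.25
AHP_MU = 0.94


@pytest.fixture(scope="session")
def stim_basis():
    return basis.make_stimulus_basis()


@pytest.fixture(scope="session")
def hist_basis_gs():
    return basis.make_history_basis("gain_scaling")


@pytest.fixture(scope="session")
def ground_truth_glm(stim_basis, hist_basis_gs):
    """A stable (suppressive-history) GLM with identifiable weights."""
    z = np.zeros(15)
    z[2], z[3], z[4] = 0.30, 0.20, 0.08
    wh = np.zeros(20)
    wh[:5] = [-3.0, -2.0, -1.5, -1.0, -0.5]
    wh[5], wh[7], wh[10] = -1.0, -0.4, -0.2
    b = np.log(15.0)
    return {"z": z, "wh": wh, "b": b,
            "k": z @ stim_basis.functions,
            "h": wh @ hist_basis_gs.functions}


def simulate_known_glm(truth, stim_basis, hist_basis, duration_s, stim_seed,
                       sim_seed):
    """Simulate spikes from the ground-truth GLM on unit white noise."""
    rng = np.random.default_rng(stim_seed)
    n = int(duration_s * 1000)
    stim = stimulus.StimulusTrace(
        values=rng.standard_normal(n), mean_mu=0.0, sd_spec=1.0,
        seed=stim_seed,
    )
    Xs = _causal_cols(stim.values, stim_basis.functions, 0)
    drive = Xs @ truth["z"] + truth["b"]
    y, fail = _sim_kernel(
        drive, np.ascontiguousarray(truth["h"]), DT, 0, 1.0, sim_seed, 50.0
    )
    assert fail < 0, "ground-truth GLM must not run away"
    spikes = hh.SpikeTrain(
        spike_times=(np.flatnonzero(y) + 0.5) * 1e-3, duration=duration_s
    )
    return stim, spikes


@pytest.fixture(scope="session")
def glm_train_short(ground_truth_glm, stim_basis, hist_basis_gs):
    """120 s of spikes simulated from the ground-truth GLM."""
    return simulate_known_glm(ground_truth_glm, stim_basis, hist_basis_gs,
                              120.0, stim_seed=5, sim_seed=7)


@pytest.fixture(scope="session")
def short_gs_run(gs_params):
    """30 s gain-scaling HH run at the ~10 spk/s operating point."""
    stim = stimulus.generate_white_noise(GS_MU, 1.0, 30.0, seed=301)
    spikes = hh.simulate_spikes(gs_params, stim)
    return stim, spikes


def poisson_spike_train(rate_fn, duration_s, seed):
    """Inhomogeneous-Poisson spike train with per-1 ms-bin rates (spk/s)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * 1000)
    t = (np.arange(n) + 0.5) * 1e-3
    lam = np.broadcast_to(np.asarray(rate_fn(t), dtype=float), (n,))
    counts = rng.poisson(lam * 1e-3)
    times = []
    for i in np.flatnonzero(counts):
        c = counts[i]
        for j in range(c):
            times.append((i + (j + 0.5) / c) * 1e-3)
    return hh.SpikeTrain(spike_times=np.asarray(times), duration=duration_s)
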