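"""Poisson GLM: links, likelihood, design causality, fitting, simulation."""

import numpy as np
import pytest

from glmadapt import basis, glm, hh, stimulus
from glmadapt.glm import DT, DesignMatrix, build_design, inverse_link
from tests.conftest import simulate_known_glm


def random_design(rng, T=3000, rate=20.0, stim_basis=None, hist_basis=None):
    stim_basis = stim_basis or basis.make_stimulus_basis()
    stim = stimulus.StimulusTrace(
        values=rng.standard_normal(T), mean_mu=0.0, sd_spec=1.0, seed=0
    )
    counts = rng.poisson(rate * DT, T)
    times = (np.flatnonzero(counts) + 0.5) * 1e-3
    spikes = hh.SpikeTrain(spike_times=times, duration=T * 1e-3)
    return build_design(stim, spikes, stim_basis, hist_basis)


class TestLinks:
    def test_exponential_at_zero(self):
        assert inverse_link("exp")(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_softpower_at_zero(self):
        f = inverse_link("softpower", 2)
        assert f(np.array([0.0]))[0] == pytest.approx(np.log(2.0) ** 2)

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_softpower_asymptote(self, p):
        f = inverse_link("softpower", p)
        x = np.array([100.0])
        assert f(x)[0] == pytest.approx(100.0**p, rel=1e-3)

    def test_numerical_stability_at_extremes(self):
        for link in (inverse_link("exp"), inverse_link("softpower", 3)):
            lam, dlam = link.with_grad(np.array([-500.0, 500.0]))
            assert np.all(np.isfinite(dlam[:1]))
            assert lam[0] >= 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            inverse_link("identity")
        with pytest.raises(ValueError):
            inverse_link("softpower")


class TestLikelihood:
    @pytest.mark.parametrize("link,power", [("exp", None), ("softpower", 2),
                                            ("softpower", 5)])
    def test_gradient_matches_finite_differences(self, link, power):
        rng = np.random.default_rng(0)
        d = random_design(rng, T=2500, hist_basis=basis.make_history_basis(
            "gain_scaling"))
        m = glm.SpikeTrainGLM([d], link=link, power=power)
        w = 0.05 * rng.standard_normal(m.n_params)
        _, g = m.loglike_and_score(w)
        eps = 1e-6
        idx = rng.choice(m.n_params, size=8, replace=False)
        for i in idx:
            e = np.zeros(m.n_params)
            e[i] = eps
            g_fd = (m.loglike(w + e) - m.loglike(w - e)) / (2 * eps)
            assert g[i] == pytest.approx(g_fd, rel=1e-5, abs=1e-7)

    def test_homogeneous_poisson_closed_form(self):
        rng = np.random.default_rng(1)
        d = random_design(rng, T=4000)
        m = glm.SpikeTrainGLM([d])
        r = 17.0
        w = np.zeros(m.n_params)
        w[-1] = np.log(r)
        expected = np.sum(-r * DT + d.y * np.log(r))
        assert m.loglike(w) == pytest.approx(expected)

    def test_empty_segment_leaves_stimulus_gradient_unchanged(self):
        rng = np.random.default_rng(2)
        d = random_design(rng, T=3000)
        empty = DesignMatrix(
            X=np.zeros((500, d.n_params)), y=np.zeros(500),
            n_stim=d.n_stim, n_hist=d.n_hist,
        )
        w = 0.05 * rng.standard_normal(d.n_params)
        g1 = glm.SpikeTrainGLM([d]).score(w)
        g2 = glm.SpikeTrainGLM([d, empty]).score(w)
        assert np.allclose(g1[: d.n_stim], g2[: d.n_stim])


class TestDesign:
    def test_zero_stimulus_no_spikes_gives_intercept_only(self, stim_basis,
                                                          hist_basis_gs):
        T = 1000
        stim = stimulus.StimulusTrace(values=np.zeros(T), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        spikes = hh.SpikeTrain(spike_times=np.array([]), duration=T * 1e-3)
        d = build_design(stim, spikes, stim_basis, hist_basis_gs)
        assert np.all(d.X[:, :-1] == 0.0)
        assert np.all(d.X[:, -1] == 1.0)

    def test_single_spike_history_impulse_response(self, stim_basis,
                                                   hist_basis_gs):
        T = 1200
        t0 = 400
        stim = stimulus.StimulusTrace(values=np.zeros(T), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        spikes = hh.SpikeTrain(spike_times=np.array([(t0 + 0.5) * 1e-3]),
                               duration=T * 1e-3)
        d = build_design(stim, spikes, stim_basis, hist_basis_gs,
                         drop_warmup=False)
        hist_cols = d.X[:, d.n_stim : d.n_stim + d.n_hist]
        # column j at bin t0 + k equals basis function j at lag k
        for k in (1, 2, 5, 50, 150):
            assert np.allclose(hist_cols[t0 + k],
                               hist_basis_gs.functions[:, k - 1])
        # strictly causal: nothing at or before the spike bin (up to FFT
        # round-off)
        assert np.allclose(hist_cols[: t0 + 1], 0.0, atol=1e-10)

    def test_history_shift_equivariance(self, stim_basis, hist_basis_gs):
        T = 2000
        rng = np.random.default_rng(3)
        stim = stimulus.StimulusTrace(values=np.zeros(T), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        bins = np.sort(rng.choice(np.arange(100, T - 100), 40, replace=False))
        sp1 = hh.SpikeTrain(spike_times=(bins + 0.5) * 1e-3, duration=T * 1e-3)
        sp2 = hh.SpikeTrain(spike_times=(bins + 1.5) * 1e-3, duration=T * 1e-3)
        d1 = build_design(stim, sp1, stim_basis, hist_basis_gs,
                          drop_warmup=False)
        d2 = build_design(stim, sp2, stim_basis, hist_basis_gs,
                          drop_warmup=False)
        h1 = d1.X[:, d1.n_stim : d1.n_stim + d1.n_hist]
        h2 = d2.X[:, d2.n_stim : d2.n_stim + d2.n_hist]
        assert np.allclose(h1[:-1], h2[1:])

    def test_stimulus_causality(self, stim_basis):
        """Perturbing the stimulus in bin t never changes the design rows
        (hence rates) at earlier bins."""
        T = 1500
        rng = np.random.default_rng(4)
        vals = rng.standard_normal(T)
        stim1 = stimulus.StimulusTrace(values=vals, mean_mu=0.0, sd_spec=1.0,
                                       seed=0)
        vals2 = vals.copy()
        t_pert = 800
        vals2[t_pert] += 5.0
        stim2 = stimulus.StimulusTrace(values=vals2, mean_mu=0.0, sd_spec=1.0,
                                       seed=0)
        spikes = hh.SpikeTrain(spike_times=np.array([]), duration=T * 1e-3)
        d1 = build_design(stim1, spikes, stim_basis, None, drop_warmup=False)
        d2 = build_design(stim2, spikes, stim_basis, None, drop_warmup=False)
        assert np.allclose(d1.X[:t_pert], d2.X[:t_pert])
        assert not np.allclose(d1.X[t_pert:], d2.X[t_pert:])

    def test_length_mismatch_rejected(self, stim_basis):
        stim = stimulus.StimulusTrace(values=np.zeros(100), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        spikes = hh.SpikeTrain(spike_times=np.array([]), duration=0.2)
        with pytest.raises(ValueError):
            build_design(stim, spikes, stim_basis, None)


class TestFitting:
    def test_multistart_agreement_under_concavity(self):
        """Exp-link refits from 5 random initialisations agree in LL."""
        rng = np.random.default_rng(5)
        d = random_design(rng, T=4000, rate=25.0,
                          hist_basis=basis.make_history_basis("gain_scaling"))
        m = glm.SpikeTrainGLM([d])
        lls = [m.fit(n_starts=1, seed=s).llf for s in range(2)]
        fits = glm.SpikeTrainGLM([d]).fit(n_starts=5, seed=11)
        lls.append(fits.llf)
        assert max(lls) - min(lls) < 1e-5 * abs(np.mean(lls))

    def test_recovery_improves_with_training_duration(
        self, ground_truth_glm, stim_basis, hist_basis_gs
    ):
        errs = {}
        for dur, stim_seed in ((60.0, 61), (240.0, 62)):
            stim, spikes = simulate_known_glm(
                ground_truth_glm, stim_basis, hist_basis_gs, dur,
                stim_seed=stim_seed, sim_seed=63,
            )
            d = build_design(stim, spikes, stim_basis, hist_basis_gs)
            m = glm.SpikeTrainGLM([d])
            m.stim_basis, m.hist_basis = stim_basis, hist_basis_gs
            fit = m.fit()
            k_est = fit.stim_weights @ stim_basis.functions
            k_true = ground_truth_glm["k"]
            errs[dur] = np.linalg.norm(k_est - k_true) / np.linalg.norm(k_true)
        assert errs[240.0] < errs[60.0]
        assert errs[240.0] < 0.2

    def test_nested_history_lls_nondecreasing(self, glm_train_short):
        stim, spikes = glm_train_short
        fits = glm.nested_history_fits(
            [(stim, spikes)], variant="gain_scaling", i_values=(0, 2, 6, 15)
        )
        lls = [f.llf for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
        assert fits[0].t_hist_ms == pytest.approx(10.0)
        assert fits[-1].t_hist_ms == pytest.approx(150.0)

    def test_summary_reports_fit(self, glm_train_short, stim_basis,
                                 hist_basis_gs):
        stim, spikes = glm_train_short
        d = build_design(stim, spikes, stim_basis, hist_basis_gs)
        m = glm.SpikeTrainGLM([d])
        m.stim_basis, m.hist_basis = stim_basis, hist_basis_gs
        fit = m.fit()
        text = fit.summary()
        assert "log-likelihood" in text and "exp" in text
        assert fit.converged


class TestSimulation:
    def _null_fit(self, b, stim_basis, hist_basis, link="exp", power=None):
        d = DesignMatrix(
            X=np.ones((10, stim_basis.n_basis + hist_basis.n_basis + 1)),
            y=np.zeros(10), n_stim=stim_basis.n_basis,
            n_hist=hist_basis.n_basis,
        )
        m = glm.SpikeTrainGLM([d], link=link, power=power)
        m.stim_basis, m.hist_basis = stim_basis, hist_basis
        w = np.zeros(m.n_params)
        w[-1] = b
        return glm.GLMResults(model=m, params=w, llf=0.0, converged=True,
                              grad_norm=0.0, n_iter=0)

    def test_zero_filters_give_homogeneous_poisson(self, stim_basis,
                                                   hist_basis_gs):
        fit = self._null_fit(np.log(10.0), stim_basis, hist_basis_gs)
        stim = stimulus.StimulusTrace(values=np.zeros(100_000), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        train = fit.simulate(stim, seed=9)
        # 100 s at 10 spk/s: ~1000 spikes, sd ~ sqrt(1000)
        assert train.rate == pytest.approx(10.0, abs=1.0)

    def test_strong_refractory_filter_prevents_adjacent_spikes(
        self, stim_basis, hist_basis_gs
    ):
        fit = self._null_fit(np.log(80.0), stim_basis, hist_basis_gs)
        fit.params[stim_basis.n_basis] = -30.0  # first boxcar: lags 1-2 ms
        stim = stimulus.StimulusTrace(values=np.zeros(60_000), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        train = fit.simulate(stim, seed=10)
        assert train.n_spikes > 100
        isi = np.diff(np.flatnonzero(train.counts))
        assert np.all(isi > 2)

    def test_runaway_excitation_guard(self, stim_basis, hist_basis_gs):
        fit = self._null_fit(np.log(50.0), stim_basis, hist_basis_gs)
        fit.params[stim_basis.n_basis] = +10.0  # self-exciting history
        stim = stimulus.StimulusTrace(values=np.zeros(20_000), mean_mu=0.0,
                                      sd_spec=1.0, seed=0)
        with pytest.raises(glm.RunawayExcitationError):
            fit.simulate(stim, seed=11)

    def test_monte_carlo_rate_matches_conditional_intensity(
        self, ground_truth_glm, stim_basis, hist_basis_gs
    ):
        """Empirical rate of repeated simulations matches the model's
        average lambda_t on the same stimulus."""
        stim, spikes = simulate_known_glm(
            ground_truth_glm, stim_basis, hist_basis_gs, 30.0,
            stim_seed=71, sim_seed=72,
        )
        d = build_design(stim, spikes, stim_basis, hist_basis_gs,
                         drop_warmup=False)
        m = glm.SpikeTrainGLM([d])
        m.stim_basis, m.hist_basis = stim_basis, hist_basis_gs
        w = np.concatenate([ground_truth_glm["z"], ground_truth_glm["wh"],
                            [ground_truth_glm["b"]]])
        fit = glm.GLMResults(model=m, params=w, llf=0.0, converged=True,
                             grad_norm=0.0, n_iter=0)
        rates = [fit.simulate(stim, seed=100 + s).rate for s in range(30)]
        # the generating model's own realisation provides the expected rate
        expected = spikes.rate
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - expected) < max(4 * se, 0.05 * expected)

    def test_deterministic_given_seed(self, ground_truth_glm, stim_basis,
                                      hist_basis_gs):
        stim, _ = simulate_known_glm(ground_truth_glm, stim_basis,
                                     hist_basis_gs, 10.0, 81, 82)
        fit = self._null_fit(np.log(20.0), stim_basis, hist_basis_gs)
        a = fit.simulate(stim, seed=5)
        b = fit.simulate(stim, seed=5)
        assert np.array_equal(a.spike_times, b.spike_times)
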