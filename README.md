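# glmadapt

Generalized linear models of adaptive spiking: **gain scaling** and
**fractional differentiation** in Hodgkin–Huxley neurons.

## The problem

Single neurons adapt their spiking to the *variance* of their input.  Two
well-studied forms of this adaptation are:

- **Gain scaling** — the neuron rescales its input–output function by the
  stimulus standard deviation σ, so a spike carries the same information
  about the *normalised* stimulus regardless of overall amplitude.  In
  conductance-based models this depends on the balance of spike-generating
  conductances: it is strongest when the sodium-to-potassium conductance
  ratio G_Na/G_K is near one.
- **Fractional differentiation** — with slow afterhyperpolarization (AHP)
  currents (time constants 0.3, 1 and 6 s), the firing rate tracks a
  *fractional derivative* of order α of the stimulus-SD envelope: on a
  sinusoidal envelope of frequency f, gain ∝ f^α and the response leads the
  envelope by the frequency-independent phase φ = απ/2.

A conductance-based model reproduces both phenomena but is hard to fit to
spike data.  This package asks whether the *generalized linear model* (GLM)
— an autoregressive Poisson process whose rate is

    λ_t = f(k_stim·x_t + h_spk·y_hist,t + b)

with a stimulus filter `k_stim`, spike-history filter `h_spk`, baseline `b`
and fixed inverse link `f` (exponential, or softplus(x)^p) — can capture the
same adaptive computations.  Everything is simulated: the package contains
the two Hodgkin–Huxley simulators that generate the spike trains, the GLM
fitting machinery (raised-cosine/boxcar filter bases, maximum likelihood via
preconditioned conjugate gradients), and the analyses that quantify both
adaptations (spike-triggered distributions and the Wasserstein-1 gain-scaling
score D_σ; cycle averages and three estimators of the fractional order α).

It is aimed at computational neuroscientists studying adaptation and at
anyone who needs a tested, reusable reference implementation of
spike-train GLMs with long spike-history bases.

## Worked example

Score gain scaling in a Hodgkin–Huxley neuron with balanced conductances:

```python
from glmadapt import (HHParamsGS, calibrate_mean, generate_white_noise,
                      simulate_spikes, gain_scaling_analysis)

params = HHParamsGS(G_Na=1000, G_K=1000)        # pS/um^2
mu = calibrate_mean(params, seed=11)            # ~10 spk/s at sigma = 1
data = {}
for sigma in (1.0, 2.0):
    stim = generate_white_noise(mu, sigma, duration=300.0, seed=int(100 * sigma))
    data[sigma] = (stim, simulate_spikes(params, stim))
res = gain_scaling_analysis(data)
print(f"mu = {mu:.3f}, rate at sigma=1: {res.mean_rate[1.0]:.1f} spk/s, "
      f"D_2 = {res.D2:.4f}")
```

prints

```
mu = 0.251, rate at sigma=1: 10.2 spk/s, D_2 = 0.0265
```

`D_2` is the Wasserstein-1 distance between the spike-triggered
distributions of the normalised filtered stimulus at σ = 1 and σ = 2; values
near zero mean the two distributions coincide, i.e. the neuron rescales its
input gain by σ.  At an unbalanced pair (G_Na=700, G_K=1400) the same
analysis gives D_2 ≈ 0.23 — no gain scaling.

Fit a GLM to those spike trains and simulate from it:

```python
from glmadapt import SpikeTrainGLM

model = SpikeTrainGLM.from_trains(
    [(stim, spikes, sigma) for sigma, (stim, spikes) in data.items()],
    hist_basis="gain_scaling",    # 5 refractory boxcars + 15 cosines to 150 ms
)
fit = model.fit()                 # concave MLE, conjugate gradients
print(fit.summary())
glm_spikes = fit.simulate(data[1.0][0], seed=0)
```

The two experiment recipes (`run_gain_scaling_experiment`,
`run_fracdiff_experiment` in `glmadapt.pipeline`) orchestrate the full
protocols — conductance sweeps, nested spike-history fits, predictive
pseudo-R², filter PCA — with seeded, cached, resumable runs, and are also
exposed on the command line:

```bash
glmadapt analyze-gainscaling --seed 1 --out results/       # desk scale
glmadapt analyze-fracdiff --seed 1 --scale full --out ...  # full protocol, long
```

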