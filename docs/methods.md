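# Methods

This note documents the models, estimators and numerical choices behind
`glmadapt`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the package's synthetic data does and does not
emulate.

## Stimulus model

All inputs are injected currents sampled independently every 1 ms and held
constant within the bin (zero-order hold on the integration grid).  The
flat protocol draws each bin from N(μ, (4μσ)²) with σ ∈ {1.0, 1.3, 1.6,
2.0}; the mean is tied to the SD so that scaling σ scales the fluctuations
while the operating point is set by μ alone.  The variance-modulated
protocols replace the constant multiplier σ by a periodic envelope

- square: f_p(t, σ) = 1 + (σ−1)·⌊½ sin(2πt/p) + 1⌋, which equals σ on the
  half-cycle where sin ≥ 0 and 1 elsewhere;
- sine:   f_p(t, σ) = 1 + (σ−1)(½ sin(2πt/p) + ½), smoothly spanning [1, σ];

and the per-bin SD is 4μ·f_p(t, σ).  One wording ambiguity had to be
resolved here: the modulated protocol describes 4μf_p as a "variance" while
the flat protocol unambiguously uses 4μσ as a standard deviation.  We treat
4μf_p as the *standard deviation*, so that f_p plays exactly the role σ
plays in the flat protocol and the two protocols agree at σ = 1; the
alternative reading would give the two protocols different units.

μ is calibrated per neuron model by bisection against the simulated firing
rate (100 s per evaluation, fixed calibration seed, tolerance 0.5 spk/s)
to a baseline of ~10 spk/s at σ = 1.  The simulated rate is empirically
nondecreasing in μ over the bracket (verified in the test suite), which
justifies bisection.  Parameter sets that spike with zero input are
rejected; for the variable-conductance model this excludes the
high-G_Na/low-G_K corner of the grid (every grid pair with ratio ≥ 1.7).

## Hodgkin–Huxley simulators

Two single-compartment variants generate all spike-train data.

**Gain-scaling model.**  Mainen-style kinetics with variable total sodium
and potassium conductances G_Na, G_K ∈ [600, 2000] pS/μm² and a fixed leak
of 0.4 pS/μm²; with C = 1 μF/cm² (1 pS/μm² = 0.1 mS/cm²) the resting
membrane time constant is 25 ms, which doubles as the unit-conversion
self-check.  The potassium current is *first order* in its activation gate
(a Kv-style channel), not n⁴.  The printed rate constants of this kinetic
family (e.g. α_m = 182(V+35)/(1−exp(−(V+35)/9))) are the standard ms⁻¹
values scaled by 1000, i.e. they are per-second rates with V in mV; the
integrator converts them to ms⁻¹.  This interpretation is validated
behaviourally: the model rests near −72 mV, relaxes with τ ≈ 25 ms,
calibrates to 10 spk/s at plausible current levels, and reproduces the
known dependence of gain scaling on G_Na/G_K.  Sodium inactivation uses the
sigmoid steady state h_∞ = 1/(1+exp((V+65)/6.2)) with τ_h from the rate
functions, and m_∞ = α_m τ_m (the m/n subscript confusion in some printings
of these equations is resolved by symmetry with n_∞).

**AHP model.**  The classical squid-axon equations (n⁴ potassium kinetics,
rates in ms⁻¹, E_L = −54.4 mV) plus three afterhyperpolarization
conductances G_AHP = (0.05, 0.006, 0.004)·G_L with reversal −100 mV.  Their
activations a_i decay as da_i/dt = −a_i/τ_i with τ = (0.3, 1, 6) s and jump
by +1 at each spike.  Because the increments feed back into the dynamics,
spike detection runs *online* inside the integrator; the gain-scaling model
can be detected offline from the voltage trace with the identical rule.

Both models are integrated with fixed-step RK4 at dt = 0.01 ms (the test
suite verifies ~4th-order step-halving convergence and < 0.1 ms spike-time
shifts under dt halving).  Spikes are upward crossings of −10 mV — the
first sample at or above threshold following a sample below it — separated
by at least 2 ms.  Integration starts at the I = 0 resting fixed point
(found by 1-D root bracketing of the steady-state current) and runs 1 s at
the constant mean current before the stimulus starts, so rate estimates are
not biased by the onset transient; AHP states still accumulate spikes
during this settling second.  A state with |V| > 500 mV (or NaN) aborts
integration with a timestamped error.

## Gain-scaling quantification

For each σ: (1) the spike-triggered average (STA) of the mean-subtracted
stimulus over a 100 ms causal window (lags 0–99 ms, matching the GLM
stimulus-filter range); (2) the projection s(t) = Σ_k STA(k)(x(t−k) − μ);
(3) histograms of ŝ = s/σ at spike bins and at all bins with bin width 0.1
on [−5, 5] (open-ended edge bins, covering ±5 SD of a standard normal); and
(4) the score

    D_σ = W1(p_1(ŝ|spk), p_σ(ŝ|spk)),

the Wasserstein-1 distance between the spike-triggered distributions at
baseline and at σ, computed in closed form as Σ|ΔCDF|·binwidth.  D near 0
means the neuron rescales its input gain by σ.

"Normalised STA" is ambiguous, and the choice matters because ŝ must be
comparable across σ.  Default: the STA is scaled so that ŝ has unit
variance on the same trace (`norm="projected_variance"`), which makes the
marginal distribution of ŝ a standard normal for Gaussian input — exactly
the property the probabilistic definition of the input–output function
R̂(ŝ) = p(ŝ|spk)p(spk)/p(ŝ) assumes.  A unit-L2-norm convention is
available behind `norm="unit_norm"`.  The I/O curve is reported only over
bins with ≥ 10 prior samples (variance control of the ratio estimator).
D_2 is the headline score; D_1.3 and D_1.6 are retained in the tables.

## GLM

Spike counts in 1 ms bins are Poisson with rate λ_t = f(k_stim·x_t +
h_spk·y_hist,t + b).  The stimulus term includes the current bin (lag 0):
the simulated neuron's spike in a bin is driven by the current in that same
bin, so the lag-0 term carries real signal; the history term is strictly
causal (lags ≥ 1 ms).  Filters are parameterised in bases:

- stimulus: 15 raised cosines, log-spaced peaks 0–100 ms, c = 0.02;
- history: 5 boxcars of width 2 ms tiling the first 10 ms (absolute
  refractory period) plus N raised cosines with c = 0.05 — N = 15 with
  peaks 10–150 ms for gain scaling, N = 25 with peaks 10 ms–16 s for
  fractional differentiation.

A raised cosine g_j(t) = cos((log(t+c) − φ_j)/a)/2 + 1/2 on
|log(t+c) − φ_j| ≤ aπ, with φ_j evenly spaced in log(T/1000 + c) and
a = 2(φ₂−φ₁)/π.

Fitting maximises the pooled Poisson log-likelihood Σ_t −λ_tΔt + y_t log λ_t
across all training conditions by conjugate gradients with analytic
gradients, run in a Cholesky-whitened parameterisation of the design
(pure preconditioning — the optimum is unchanged, but the raw basis columns
differ in scale by orders of magnitude and unpreconditioned CG needs ~5×
more iterations), with an L-BFGS-B polish if CG stalls short of the 10⁻⁶
scaled-gradient tolerance.  With the exponential link the problem is
concave, so the null model (zero filters, b = log mean rate) is the single
start and the optimum is global; soft-power links f(x) = softplus(x)^p,
p ∈ {2,...,5}, are non-concave and use three seeded starts with
best-likelihood selection.  No regularisation is applied (plain MLE).

Initial bins whose filters would extend before the data start are dropped
from the likelihood, capped at a quarter of each condition's length: for
the 25 s fractional-differentiation history basis a full-filter drop would
swallow short desk-scale conditions entirely, so bins past the cap use the
zero-padded history (equivalent to assuming silence before the segment).
At production scale (≥ 3200 s per condition) the cap never binds.

Nested history fits reuse one full design matrix and fit column subsets
with the boxcars plus the first i cosines, i = 0..N, warm-started from the
previous fit; because all fits share identical likelihood rows, training
log-likelihood is provably nondecreasing in i.  Each fit is labelled by
T_hist, the peak time of its last cosine (10 ms — the end of the boxcar
section — for i = 0).

Simulation from a fitted GLM is sequential: the stimulus drive is
precomputed, then each bin's count is drawn Poisson(λ_tΔt) and immediately
propagated through the reconstructed history filter into future bins.  A
bin with λ_tΔt > 50 aborts with a runaway-excitation error (exp-link GLMs
with positive history weights can self-excite).

## Fractional differentiation

The reference operator is the Grünwald–Letnikov fractional derivative with
binomial weights w_k = (−1)^k C(α,k), scaled by dt^(−α).  For cycle-length
signals the weights are folded periodically (the operator becomes exactly
circulant, its tail summed over ≥ 2000 taps), which gives the steady-state
response of the ideal differentiator: on sin(2πft), gain (2πf)^α and phase
lead απ/2 — verified against the closed form to 1% / 0.01 rad on finely
sampled sinusoids.  Note the 30-bin cycle grid itself discretises the
phase: the circulant operator's phase at the first harmonic is
α(π/2 − π/30), a ~7% downward bias that affects the operator-generated
*oracle* data equally and is far inside the estimator tolerances used.

Responses are summarised by cycle averages: mean rate in 30 phase bins
(left-closed, edge values snapped upward within round-off) across all
cycles after discarding the first two as burn-in.  From these:

- **gain estimator**: slope of log(first-harmonic amplitude) on log(f)
  across ≥ 3 periods (gain ∝ f^α);
- **phase estimator**: α = 2·mean(φ)/π with φ the first-harmonic phase
  lead relative to the envelope's sine phase;
- **square-wave estimator**: α minimising the summed squared error of
  scale·FD_α(envelope) + baseline against the square-wave cycle averages of
  all periods jointly (scale and a pooled baseline profiled out by linear
  least squares at each α; α by a 21-point grid scan refined by bounded
  1-D search).  Periods are weighted equally.  A per-period-baseline
  variant sits behind a flag.

Exponential time constants of the square-wave responses are fitted per
half-cycle with r(t) = r_∞ + A·exp(−t/τ) (τ log-parameterised; a
non-decaying half-cycle returns the period as a boundary flag).

## Model evaluation

Predictive quality uses the deviance-based pseudo-R²,
1 − [LL_sat − LL_model]/[LL_sat − LL_null], with the saturated model
placing expected count equal to the observed count in each bin and the
null model the constant mean rate.  It is exactly 1 for the saturated
prediction, exactly 0 for the null, and negative when a model generalises
worse than the mean rate — a meaningful outcome for GLMs trained at one σ
and tested at another.  Test stimuli are fresh 32 s draws from a reserved
seed stream; for the fractional-differentiation protocol the test envelope
is a 4 s period at σ = 2.

Filter geometry across the conductance grid uses mean-centred covariance
PCA (no per-lag variance scaling — filters share units) on filters stacked
as rows at 1 ms resolution; history filters are truncated below 20 ms so
the refractory period does not dominate.  PC projections are correlated
(Pearson) with the raw ratio G_Na/G_K and with the HH D_2 score; components
are sign-oriented so each correlates nonnegatively with its covariate, with
flips recorded.

## Problem sizes and seeding

The full protocols are expensive (the production gain-scaling grid is 225
conductance pairs × 4 σ × 2000 s; the production envelope protocol is 7
periods × 3200 s × 2 envelopes × 3 σ).  These settings ship behind the
`--scale full` configuration and are marked long-running.  The package's
desk-scale defaults, used by the test suite and the acceptance script, are:
a six-pair conductance sweep spanning ratios 0.50–1.67 with 300 s per
σ ∈ {1, 2}; and envelope periods 1–16 s with 12 cycles per period (10
analysed).  Near the gain-scaling optimum the D_2 surface is shallow: the
separation between neighbouring grid ratios (1.0 vs 1.17) is of the same
order as the W1 estimator's finite-sample floor at ~3000 spikes per
condition (a few ×10⁻²·√(2000 s/T)), so the precise argmin among the two
best pairs is less certain than the strong ordering against all other
ratios.  At desk scale the
full-grid quantities (PCA variance fractions, phase-lead and time-constant
R², predicted-variance fractions) are replaced by their qualitative
orderings: two-component dominance of the filter PCA and the GLM's α
approaching the HH value from below as T_hist grows.

Every random draw derives from a single master seed through SHA-256 hashing
of a (seed, tag...) tuple, with disjoint tag streams for calibration,
training, GLM simulation and test stimuli; derived seeds are < 2³¹.
Identical seeds give bit-identical stimuli, spike trains and fits.
Experiment runs cache per-unit results keyed by a content hash of their
parameters and are idempotent on re-run.

## What the synthetic data does not emulate

The simulators generate exactly the stimulus family the analyses assume:
Gaussian injected current, single compartment, deterministic channel
kinetics.  Real neurons receive conductance inputs filtered by dendrites,
have stochastic channels and non-Gaussian input statistics, and express
both adaptive computations simultaneously; none of this is modelled, so
passing tests demonstrate that the GLM captures these two computations in
the idealised biophysical setting, not that it suffices for arbitrary
in-vitro data.  Other known limitations: a fixed leak conductance (the
optimal G_Na/G_K ratio depends on it); the 2 ms refractory rule merges
genuine doublets closer than 2 ms; the GL operator's finite tail leaves a
small DC offset that is absorbed by the fitted baseline; and the
symmetrized-KL / Jensen–Shannon alternatives to the Wasserstein score are
not implemented (they are reported elsewhere to behave similarly).
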