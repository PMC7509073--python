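"""Autoregressive Poisson GLMs of spiking.

The spike count in each 1 ms bin is Poisson with rate

    lambda_t = f(k_stim . x_t + h_spk . y_hist,t + b)

where x_t is the stimulus preceding (and including) bin t, y_hist,t the
strictly causal spike-count history, and f the inverse link (exponential by
default, or the soft-power family softplus(x)^p).  Filters are
parameterised in raised-cosine/boxcar bases (see :mod:`glmadapt.basis`) and
fitted by maximum likelihood; with the exponential link the log-likelihood
is concave, so conjugate gradients from the null model finds the global
optimum.  Fits pool the log-likelihood over any number of stimulus
conditions.

The module follows the statsmodels convention: :class:`SpikeTrainGLM` is the
model object (data + basis + link) and :meth:`SpikeTrainGLM.fit` returns a
:class:`GLMResults` carrying the estimates, reconstructed filters,
diagnostics and a ``summary()`` table, plus ``simulate()`` for generating
spike trains from the fitted process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .basis import BasisSet, make_history_basis, make_stimulus_basis
from .hh import SpikeTrain
from .stimulus import StimulusTrace

DT = 1e-3  # bin width, seconds

__all__ = [
    "DesignMatrix",
    "SpikeTrainGLM",
    "GLMResults",
    "RunawayExcitationError",
    "inverse_link",
    "build_design",
    "nested_history_fits",
    "simulate_glm",
]


class RunawayExcitationError(RuntimeError):
    """Simulated rate exceeded the self-excitation guard (lambda*dt > 50)."""


# ---------------------------------------------------------------------------
# Inverse links


class _ExpLink:
    name = "exp"

    def __call__(self, x):
        return np.exp(x)

    def with_grad(self, x):
        lam = np.exp(x)
        return lam, lam

    def log(self, x):
        """log f(x), numerically safe."""
        return x


class _SoftPowerLink:
    def __init__(self, p: int):
        if p < 1:
            raise ValueError("soft-power exponent must be >= 1")
        self.p = p
        self.name = f"softpower({p})"

    def __call__(self, x):
        return np.logaddexp(0.0, x) ** self.p

    def with_grad(self, x):
        sp = np.logaddexp(0.0, x)
        lam = sp**self.p
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        dlam = self.p * sp ** (self.p - 1) * sig
        return lam, dlam

    def log(self, x):
        sp = np.logaddexp(0.0, x)
        return self.p * np.log(np.maximum(sp, 1e-300))


def inverse_link(kind: str = "exp", p: int | None = None):
    """Inverse-link factory: ``"exp"`` or ``"softpower"`` with exponent p.

    Both are numerically stable for large |x|: softplus(x)^p behaves as x^p
    for x -> inf and decays like exp(p*x) for x -> -inf.
    """
    if kind == "exp":
        return _ExpLink()
    if kind == "softpower":
        if p is None:
            raise ValueError("softpower link needs an exponent p")
        return _SoftPowerLink(p)
    raise ValueError(f"unknown link {kind!r}")


# ---------------------------------------------------------------------------
# Design matrices


@dataclass(frozen=True)
class DesignMatrix:
    """Per-bin regressors for one stimulus condition.

    ``X`` columns are [stimulus-basis projections | history-basis
    projections | intercept]; ``y`` the spike counts.  The first
    ``n_warmup`` bins (where the filters would extend before time 0) are
    dropped from both.  History columns at bin t depend only on spikes in
    bins < t.
    """

    X: np.ndarray
    y: np.ndarray
    n_stim: int
    n_hist: int
    label: object = None
    n_warmup: int = 0
    dt: float = DT

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]


def _causal_cols(x: np.ndarray, funcs: np.ndarray, first_lag: int) -> np.ndarray:
    """Columns of causal convolutions of x with each basis row.

    ``first_lag`` is the lag (in bins) of the first basis sample: 0 for the
    stimulus basis, 1 for the strictly causal history basis.
    """
    T = len(x)
    cols = np.empty((T, funcs.shape[0]))
    for j, g in enumerate(funcs):
        full = fftconvolve(x, g)
        if first_lag == 0:
            cols[:, j] = full[:T]
        else:
            cols[1:, j] = full[: T - 1]
            cols[0, j] = 0.0
    return cols


def build_design(
    stim: StimulusTrace,
    spikes: SpikeTrain,
    stim_basis: BasisSet,
    hist_basis: BasisSet | None,
    label: object = None,
    drop_warmup: bool | int = True,
) -> DesignMatrix:
    """Assemble the design matrix for one (stimulus, spike train) pair.

    ``drop_warmup`` controls how many initial bins (where the filters would
    extend before time 0 and the causal convolutions are zero-padded) are
    excluded from the likelihood: ``True`` drops the full filter length,
    capped at a quarter of the trace so that conditions shorter than the
    longest history filter keep likelihood mass (bins past the cap use the
    zero-padded history, i.e. assume silence before the segment); ``False``
    drops nothing; an int drops exactly that many bins.
    """
    x = stim.values
    y = spikes.counts.astype(np.float64)
    if len(x) != len(y):
        raise ValueError("stimulus and spike train must share duration and dt")
    Xs = _causal_cols(x, stim_basis.functions, first_lag=0)
    blocks = [Xs]
    n_hist = 0
    warm = stim_basis.n_lags
    if hist_basis is not None:
        Xh = _causal_cols(y, hist_basis.functions, first_lag=1)
        blocks.append(Xh)
        n_hist = hist_basis.n_basis
        warm = max(warm, hist_basis.n_lags + 1)
    blocks.append(np.ones((len(x), 1)))
    X = np.hstack(blocks)
    if drop_warmup is True:
        n_warmup = min(warm, len(x) // 4)
    elif drop_warmup is False:
        n_warmup = 0
    else:
        n_warmup = int(drop_warmup)
    return DesignMatrix(
        X=X[n_warmup:], y=y[n_warmup:], n_stim=stim_basis.n_basis,
        n_hist=n_hist, label=label, n_warmup=n_warmup,
    )


# ---------------------------------------------------------------------------
# Model


class SpikeTrainGLM:
    """Poisson GLM of a spike train given stimulus and spike history.

    Parameters
    ----------
    designs
        One :class:`DesignMatrix` per training condition; the fit pools
        their log-likelihoods.  All must share the same column layout.
    link, power
        Inverse-link specification (``"exp"``, or ``"softpower"`` with
        exponent ``power`` in {2, 3, 4, 5}).
    """

    def __init__(self, designs, link: str = "exp", power: int | None = None):
        if isinstance(designs, DesignMatrix):
            designs = [designs]
        if not designs:
            raise ValueError("at least one design matrix is required")
        p0 = designs[0]
        for d in designs:
            if (d.n_params, d.n_stim, d.n_hist) != (p0.n_params, p0.n_stim, p0.n_hist):
                raise ValueError("designs must share the same column layout")
        self.designs = list(designs)
        self.link = inverse_link(link, power) if isinstance(link, str) else link
        self.n_params = p0.n_params
        self.n_stim = p0.n_stim
        self.n_hist = p0.n_hist
        self._n_total = sum(d.n_bins for d in self.designs)

    @classmethod
    def from_trains(
        cls,
        data,
        stim_basis: BasisSet | None = None,
        hist_basis: BasisSet | str | None = "gain_scaling",
        link: str = "exp",
        power: int | None = None,
    ) -> "SpikeTrainGLM":
        """Build the model from (stimulus, spikes[, label]) tuples."""
        if stim_basis is None:
            stim_basis = make_stimulus_basis()
        if isinstance(hist_basis, str):
            hist_basis = make_history_basis(hist_basis)
        designs = []
        for item in data:
            stim, spikes = item[0], item[1]
            label = item[2] if len(item) > 2 else None
            designs.append(build_design(stim, spikes, stim_basis, hist_basis, label))
        model = cls(designs, link=link, power=power)
        model.stim_basis = stim_basis
        model.hist_basis = hist_basis
        return model

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Pooled Poisson log-likelihood (up to the y! constant)."""
        ll = 0.0
        for d in self.designs:
            eta = d.X @ params
            lam = self.link(eta)
            ll += float(-np.sum(lam) * d.dt + d.y @ self.link.log(eta))
        return ll

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`loglike` in basis-weight space."""
        g = np.zeros(self.n_params)
        for d in self.designs:
            eta = d.X @ params
            lam, dlam = self.link.with_grad(eta)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(d.y > 0, d.y / np.maximum(lam, 1e-300), 0.0)
            g += d.X.T @ ((w - d.dt) * dlam)
        return g

    def loglike_and_score(self, params):
        ll = 0.0
        g = np.zeros(self.n_params)
        for d in self.designs:
            eta = d.X @ params
            lam, dlam = self.link.with_grad(eta)
            ll += float(-np.sum(lam) * d.dt + d.y @ self.link.log(eta))
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(d.y > 0, d.y / np.maximum(lam, 1e-300), 0.0)
            g += d.X.T @ ((w - d.dt) * dlam)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood (rate underflow)")
        return ll, g

    def _null_params(self) -> np.ndarray:
        """Null starting point: zero filters, intercept matching the mean rate."""
        total_spikes = sum(d.y.sum() for d in self.designs)
        rate = max(total_spikes / (self._n_total * DT), 1e-3)
        w = np.zeros(self.n_params)
        if self.link.name == "exp":
            w[-1] = np.log(rate)
        else:
            # softplus(x)^p = rate  =>  x = log(exp(rate^(1/p)) - 1)
            target = rate ** (1.0 / self.link.p)
            w[-1] = np.log(np.expm1(target)) if target < 30 else target
        return w

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_params: np.ndarray | None = None,
        method: str = "CG",
        gtol: float = 1e-6,
        maxiter: int = 2000,
        n_starts: int | None = None,
        seed: int = 0,
    ) -> "GLMResults":
        """Maximise the pooled log-likelihood.

        Conjugate gradients on the per-bin-scaled objective, with an
        L-BFGS-B fallback when CG stalls.  The optimisation runs in a
        whitened parameterisation (Cholesky factor of the pooled Gram matrix
        X'X) purely as a preconditioner, which makes the near-quadratic
        exp-link objective close to isotropic; reported weights are on the
        original basis scale.  The exponential-link problem is concave, so a
        single start from the null model suffices; soft-power links are
        non-concave and use ``n_starts`` seeded random starts (default 3)
        with best-likelihood selection.
        """
        from scipy.linalg import cholesky, solve_triangular

        scale = 1.0 / self._n_total
        gram = np.zeros((self.n_params, self.n_params))
        for d in self.designs:
            gram += d.X.T @ d.X
        gram /= self._n_total
        gram[np.diag_indices_from(gram)] += 1e-10 * max(gram.max(), 1.0)
        R = cholesky(gram, lower=False)  # params = solve(R, u)

        def to_params(u):
            return solve_triangular(R, u, lower=False)

        def from_params(params):
            return R @ params

        def neg(u):
            params = to_params(u)
            try:
                ll, g = self.loglike_and_score(params)
            except FloatingPointError:
                return np.inf, np.zeros_like(u)
            g_u = solve_triangular(R.T, g, lower=True)
            return -ll * scale, -g_u * scale

        if n_starts is None:
            n_starts = 1 if self.link.name == "exp" else 3
        rng = np.random.default_rng(seed)
        starts = []
        if start_params is not None:
            starts.append(np.asarray(start_params, dtype=float))
        else:
            starts.append(self._null_params())
        while len(starts) < n_starts:
            s = self._null_params()
            s[:-1] += 0.1 * rng.standard_normal(self.n_params - 1)
            starts.append(s)

        best = None
        for s in starts:
            res = minimize(neg, from_params(s), jac=True, method=method,
                           options={"gtol": gtol, "maxiter": maxiter})
            if method == "CG" and np.max(np.abs(res.jac)) > gtol:
                res2 = minimize(neg, res.x, jac=True, method="L-BFGS-B",
                                options={"gtol": gtol, "maxiter": maxiter,
                                         "ftol": 1e-14})
                if res2.fun <= res.fun:
                    res = res2
            if best is None or res.fun < best.fun:
                best = res
        grad_norm = float(np.max(np.abs(best.jac)))
        converged = grad_norm <= gtol * 10
        if not converged:
            warnings.warn(
                f"GLM fit did not reach gradient tolerance "
                f"(|grad|_inf = {grad_norm:.2e})", stacklevel=2,
            )
        return GLMResults(
            model=self,
            params=to_params(best.x),
            llf=float(-best.fun / scale),
            converged=converged,
            grad_norm=grad_norm,
            n_iter=int(best.nit),
        )


# ---------------------------------------------------------------------------
# Results


@dataclass
class GLMResults:
    """Fitted GLM: estimates, reconstructed filters and diagnostics."""

    model: SpikeTrainGLM
    params: np.ndarray
    llf: float
    converged: bool
    grad_norm: float
    n_iter: int
    t_hist_ms: float | None = None  # set by nested_history_fits

    @property
    def stim_weights(self) -> np.ndarray:
        return self.params[: self.model.n_stim]

    @property
    def hist_weights(self) -> np.ndarray:
        return self.params[self.model.n_stim : self.model.n_stim + self.model.n_hist]

    @property
    def baseline(self) -> float:
        return float(self.params[-1])

    def stimulus_filter(self, basis: BasisSet | None = None):
        """Reconstructed stimulus filter (lags_ms, values)."""
        basis = basis or getattr(self.model, "stim_basis", None)
        if basis is None:
            raise ValueError("stimulus basis not attached to the model")
        return basis.lags_ms, self.stim_weights @ basis.functions

    def history_filter(self, basis: BasisSet | None = None):
        """Reconstructed spike-history filter (lags_ms, values)."""
        basis = basis or getattr(self.model, "hist_basis", None)
        if basis is None:
            raise ValueError("history basis not attached to the model")
        return basis.lags_ms, self.hist_weights @ basis.functions

    def predict_rate(self, design: DesignMatrix) -> np.ndarray:
        """Conditional intensity lambda_t (spk/s) on a design matrix."""
        return self.model.link(design.X @ self.params)

    def simulate(self, stim: StimulusTrace, seed: int = 0,
                 hist_basis: BasisSet | None = None) -> SpikeTrain:
        """Sample a spike train from the fitted autoregressive process."""
        return simulate_glm(self, stim, seed, hist_basis=hist_basis)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Poisson spike-train GLM",
            "=" * 54,
            f"link:              {m.link.name}",
            f"conditions:        {len(m.designs)}",
            f"observations:      {m._n_total} bins of {DT*1e3:.0f} ms",
            f"parameters:        {m.n_params} "
            f"({m.n_stim} stimulus + {m.n_hist} history + 1 baseline)",
            f"log-likelihood:    {self.llf:.2f}",
            f"converged:         {self.converged} "
            f"(|grad|_inf = {self.grad_norm:.2e}, {self.n_iter} iter)",
            f"baseline b:        {self.baseline:.4f}",
        ]
        if self.t_hist_ms is not None:
            lines.append(f"T_hist:            {self.t_hist_ms:.0f} ms")
        lines.append("-" * 54)
        lines.append("stimulus weights:  "
                     + np.array2string(self.stim_weights, precision=3))
        if m.n_hist:
            lines.append("history weights:   "
                         + np.array2string(self.hist_weights, precision=3))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Nested history fits


def nested_history_fits(
    data,
    variant: str = "gain_scaling",
    link: str = "exp",
    power: int | None = None,
    stim_basis: BasisSet | None = None,
    i_values=None,
    seed: int = 0,
) -> list[GLMResults]:
    """Fit GLMs with increasing spike-history length on the same data.

    For i = 0 (refractory boxcars only) to N cosines, fits a GLM whose
    history basis keeps the first i cosines.  All fits share identical
    likelihood rows (the warm-up is set by the full basis), so training
    log-likelihood is nondecreasing in i.  Each result is tagged with
    T_hist (the peak time of the last included cosine; 10 ms for i = 0).
    ``data`` is a list of (stimulus, spikes[, label]) tuples.
    """
    if stim_basis is None:
        stim_basis = make_stimulus_basis()
    full_hist = make_history_basis(variant)
    # build the full design once; truncated fits reuse a column subset
    designs = []
    for item in data:
        stim, spikes = item[0], item[1]
        label = item[2] if len(item) > 2 else None
        designs.append(build_design(stim, spikes, stim_basis, full_hist, label))
    if i_values is None:
        i_values = range(full_hist.n_cosines + 1)
    ns, nb = stim_basis.n_basis, full_hist.n_boxcars
    fits = []
    prev = None
    for i in i_values:
        cols = list(range(ns + nb + i)) + [designs[0].n_params - 1]
        sub = [
            DesignMatrix(X=d.X[:, cols], y=d.y, n_stim=ns, n_hist=nb + i,
                         label=d.label, n_warmup=d.n_warmup)
            for d in designs
        ]
        model = SpikeTrainGLM(sub, link=link, power=power)
        model.stim_basis = stim_basis
        model.hist_basis = full_hist.truncate_cosines(i)
        if prev is not None and len(prev.params) == len(cols) - 1:
            start = np.concatenate([prev.params[:-1], [0.0], prev.params[-1:]])
        else:
            start = None
        res = model.fit(start_params=start, seed=seed)
        res.t_hist_ms = full_hist.t_hist_ms(i)
        fits.append(res)
        prev = res
    return fits


# ---------------------------------------------------------------------------
# Simulation


@njit(cache=False)
def _sim_kernel(drive, h_filt, dt, link_id, power, seed, guard):
    np.random.seed(seed)
    T = len(drive)
    L = len(h_filt)
    acc = np.zeros(T)
    y = np.zeros(T, dtype=np.int64)
    for t in range(T):
        eta = drive[t] + acc[t]
        if link_id == 0:
            lam = np.exp(eta)
        else:
            if eta > 30.0:
                sp = eta
            else:
                sp = np.log1p(np.exp(eta))
            lam = sp**power
        mean_count = lam * dt
        if mean_count > guard:
            return y, t  # runaway excitation
        c = np.random.poisson(mean_count)
        if c > 0:
            y[t] = c
            end = min(T, t + 1 + L)
            for k in range(t + 1, end):
                acc[k] += c * h_filt[k - t - 1]
    return y, -1


def simulate_glm(
    fit: GLMResults,
    stim: StimulusTrace,
    seed: int = 0,
    hist_basis: BasisSet | None = None,
    guard: float = 50.0,
) -> SpikeTrain:
    """Sample spikes sequentially from a fitted GLM on a new stimulus.

    Computes the stimulus drive k_stim . x_t + b vectorised, then samples
    bin by bin: each sampled count feeds the reconstructed history filter
    forward into future bins.  Raises :class:`RunawayExcitationError` when
    lambda_t * dt exceeds ``guard`` (self-excitation safeguard).
    """
    model = fit.model
    stim_basis = getattr(model, "stim_basis", None)
    if stim_basis is None:
        raise ValueError("stimulus basis not attached to the model")
    hist_basis = hist_basis or getattr(model, "hist_basis", None)
    Xs = _causal_cols(stim.values, stim_basis.functions, first_lag=0)
    drive = Xs @ fit.stim_weights + fit.baseline
    if hist_basis is not None and model.n_hist:
        _, h_filt = fit.history_filter(hist_basis)
    else:
        h_filt = np.zeros(1)
    link = model.link
    link_id = 0 if link.name == "exp" else 1
    power = float(getattr(link, "p", 1))
    y, fail_t = _sim_kernel(
        drive, np.ascontiguousarray(h_filt, dtype=np.float64), DT, link_id,
        power, seed & 0x7FFFFFFF, guard,
    )
    if fail_t >= 0:
        raise RunawayExcitationError(
            f"lambda*dt exceeded {guard} at t = {fail_t * DT:.3f} s"
        )
    # convert counts to spike times at bin centres (sub-bin order arbitrary)
    times = []
    for t in np.flatnonzero(y):
        c = y[t]
        for j in range(c):
            times.append((t + (j + 0.5) / c) * DT)
    return SpikeTrain(
        spike_times=np.asarray(times), duration=stim.duration,
    )
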