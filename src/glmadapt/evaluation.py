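"""Model evaluation: pseudo-R^2 and filter-geometry PCA.

The pseudo-R^2 compares the Poisson deviance of a model's per-bin rate
prediction against the null model (constant mean rate), referenced to the
saturated model that places its rate mass exactly on the observed counts:

    pseudo-R^2 = 1 - [LL_sat - LL_model] / [LL_sat - LL_null]

It is 1 for the saturated prediction, 0 for the null, and negative when the
model predicts test spikes worse than the mean rate alone — a meaningful
outcome for fits that fail to generalise across stimulus conditions.

The filter PCA characterises how fitted GLM filters vary across the
(G_Na, G_K) conductance grid: filters are stacked as rows, mean-centred,
decomposed by covariance PCA (no variance scaling, since filters share
units), and the per-neuron projections are correlated with the conductance
ratio G_Na/G_K and with the gain-scaling score D_2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

DT = 1e-3

__all__ = ["pseudo_r2", "FilterPCA", "filter_pca"]


def _poisson_ll(lam_dt: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-likelihood sum(-lam*dt + y*log(lam*dt)), 0*log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(lam_dt, 1e-300)), 0.0)
    return float(np.sum(-lam_dt + term))


def pseudo_r2(
    test_counts: np.ndarray,
    model_rate: np.ndarray,
    null_rate: float | None = None,
    dt: float = DT,
) -> float:
    """Fraction of explainable log-likelihood captured by ``model_rate``.

    Parameters
    ----------
    test_counts
        Observed spike counts per 1 ms bin of the held-out response.
    model_rate
        Predicted conditional intensity per bin, spk/s.
    null_rate
        Rate of the null model, spk/s; defaults to the mean rate of
        ``test_counts``.  The saturated reference has expected count equal
        to the observed count in every bin.
    """
    y = np.asarray(test_counts, dtype=float)
    if y.sum() == 0:
        raise ValueError("test spike train is empty: pseudo-R^2 undefined")
    lam = np.asarray(model_rate, dtype=float)
    if lam.shape != y.shape:
        raise ValueError("model_rate and test_counts must be aligned per bin")
    if null_rate is None:
        null_rate = y.mean() / dt
    ll_model = _poisson_ll(lam * dt, y)
    ll_null = _poisson_ll(np.full_like(y, null_rate * dt), y)
    ll_sat = _poisson_ll(y, y)
    return 1.0 - (ll_sat - ll_model) / (ll_sat - ll_null)


@dataclass(frozen=True)
class FilterPCA:
    """PCA of fitted filters across a conductance grid."""

    mean_filter: np.ndarray
    components: np.ndarray  # (n_components, n_lags)
    variance_explained: np.ndarray  # fractions, nonincreasing
    projections: np.ndarray  # (n_fits, n_components)
    lags_ms: np.ndarray
    ratio_correlations: list | None = None  # per PC: (r, p) vs G_Na/G_K
    d2_correlations: list | None = None  # per PC: (r, p) vs D_2
    sign_flips: np.ndarray | None = None

    @property
    def two_component_variance(self) -> float:
        """Fraction of filter variance captured by the first two PCs."""
        return float(self.variance_explained[:2].sum())


def filter_pca(
    filters: np.ndarray,
    lags_ms: np.ndarray,
    which: str = "stimulus",
    ratios: np.ndarray | None = None,
    d2_scores: np.ndarray | None = None,
    n_components: int | None = None,
    history_cutoff_ms: float = 20.0,
) -> FilterPCA:
    """Mean-centred covariance PCA over filters stacked as rows.

    For history filters the lags below ``history_cutoff_ms`` are excluded to
    avoid the strong refractory period dominating the decomposition.  When
    ``ratios`` (G_Na/G_K per fit) and/or ``d2_scores`` are given, Pearson
    correlations of each PC projection against them are reported; components
    are oriented so the correlation with their covariate is nonnegative
    (PC1 against the ratio, PC2 against D_2), with flips recorded.
    """
    F = np.asarray(filters, dtype=float)
    lags = np.asarray(lags_ms, dtype=float)
    if F.ndim != 2 or F.shape[1] != len(lags):
        raise ValueError("filters must be (n_fits, n_lags) on a common lag grid")
    if F.shape[0] < 3:
        raise ValueError("need at least 3 fits for PCA")
    if which == "history":
        keep = lags >= history_cutoff_ms
        F = F[:, keep]
        lags = lags[keep]
    n_components = n_components or min(F.shape[0] - 1, F.shape[1])
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(F)
    comps = pca.components_.copy()
    var = pca.explained_variance_ratio_

    flips = np.ones(n_components)
    covariates = {0: ratios, 1: d2_scores}
    for k in range(n_components):
        cov = covariates.get(k)
        if cov is not None and np.corrcoef(proj[:, k], cov)[0, 1] < 0:
            comps[k] *= -1
            proj[:, k] *= -1
            flips[k] = -1

    def correlate(cov):
        if cov is None:
            return None
        return [tuple(stats.pearsonr(proj[:, k], cov)) for k in range(n_components)]

    return FilterPCA(
        mean_filter=pca.mean_,
        components=comps,
        variance_explained=var,
        projections=proj,
        lags_ms=lags,
        ratio_correlations=correlate(ratios),
        d2_correlations=correlate(d2_scores),
        sign_flips=flips,
    )
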