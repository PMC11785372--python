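"""Subject embeddings and kernels from Gaussian HMMs.

Three families of subject-pair similarity are built from the same group
HMM:

* **naive** kernels on the vectorised subject-level parameters theta_n
  (optionally z-scored across subjects: naive-normalised), which treat the
  parameters as Euclidean coordinates;
* the **Fisher kernel**, an inner product of Fisher scores
  g(theta0, x_n) = d log L_{theta0}(x_n) / d theta0 — the gradient of the
  subject's log-likelihood at the group parameters, i.e. the direction the
  group model would move to better explain that subject;
* a **KL-divergence** kernel: a radial-basis function of symmetrised,
  stationary-distribution-weighted Kullback-Leibler divergences between
  subject-level HMMs.

All linear kernels are plain Gram matrices; Gaussian variants are radial
basis functions whose width tau is, by default, a multiplier of the median
pairwise training-set distance (gradient norms are data-scale dependent, so
a relative width keeps the grid meaningful across problems).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .baselines import gaussian_kl
from .hmm import HMMParams, forward_backward

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "vectorise_params",
    "devectorise_params",
    "naive_features",
    "normalise_features",
    "fisher_score",
    "fisher_scores",
    "subset_features",
    "linear_kernel",
    "gaussian_kernel",
    "naive_kernel",
    "fisher_kernel",
    "kl_hmm",
    "kl_kernel",
    "FisherScores",
    "NaiveParameterVectors",
]

_PROB_FLOOR = 1e-12


@dataclass
class FeatureSet:
    """N x D subject-feature matrix with named parameter blocks.

    block_index maps block name (pi, A, mu, sigma — or pca_state) to a
    column slice; disjoint slices covering all columns.
    """

    values: np.ndarray
    block_index: dict
    normalised: bool = False

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _block_index(K: int, M: int) -> dict:
    d0 = K
    d1 = d0 + K * K
    d2 = d1 + K * M
    d3 = d2 + K * M * M
    return {"pi": slice(0, d0), "A": slice(d0, d1), "mu": slice(d1, d2), "sigma": slice(d2, d3)}


def vectorise_params(params: HMMParams):
    """Flatten theta = [pi, A, mu, sigma] into one vector.

    Ordering: pi | A (row-major) | mu (state-major) | sigma (state-major,
    full matrices row-major), giving D = K + K^2 + K*M + K*M^2.

    Returns (vector, block_index).
    """
    vec = np.concatenate([
        params.pi.ravel(),
        params.A.ravel(),
        params.mu.ravel(),
        params.sigma.ravel(),
    ])
    return vec, _block_index(params.K, params.M)


def devectorise_params(vec: np.ndarray, K: int, M: int) -> HMMParams:
    """Inverse of :func:`vectorise_params`."""
    b = _block_index(K, M)
    return HMMParams(
        pi=vec[b["pi"]].copy(),
        A=vec[b["A"]].reshape(K, K).copy(),
        mu=vec[b["mu"]].reshape(K, M).copy(),
        sigma=vec[b["sigma"]].reshape(K, M, M).copy(),
    )


def naive_features(subject_params) -> FeatureSet:
    """Stack vectorised subject-level parameters into an N x D feature matrix."""
    rows, bi = [], None
    for p in subject_params:
        v, bi = vectorise_params(p)
        rows.append(v)
    return FeatureSet(np.vstack(rows), bi)


def normalise_features(features: FeatureSet, stats_from=None) -> FeatureSet:
    """Column-wise z-scoring using statistics from the ``stats_from`` rows.

    Statistics default to all subjects (the naive-normalised kernel's
    convention); pass the training-fold indices for a leakage-safe variant.
    Zero-variance columns are set to 0 and logged.
    """
    X = features.values
    rows = np.arange(X.shape[0]) if stats_from is None else np.asarray(stats_from)
    if rows.size == 0:
        raise ValueError("stats_from must be non-empty")
    mean = X[rows].mean(axis=0)
    sd = X[rows].std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance feature column(s) set to 0", int(dead.sum()))
    sd_safe = np.where(dead, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, dead] = 0.0
    return FeatureSet(Z, dict(features.block_index), normalised=True)


# ---------------------------------------------------------------------------
# Fisher scores
# ---------------------------------------------------------------------------


def fisher_score(group: HMMParams, x: np.ndarray, lengths=None, *,
                 transition_grad: str = "softmax", tangent: bool = False,
                 scale_by_T: bool = False):
    """Fisher score g(theta0, x): gradient of log-likelihood at the group model.

    The Gaussian blocks, in terms of forward-backward posteriors:

    * d/d mu_k     = sum_t gamma_t(k) sigma_k^-1 (x_t - mu_k)
    * d/d sigma_k  = 1/2 sum_t gamma_t(k) [sigma_k^-1 (x_t-mu_k)(x_t-mu_k)^T
                     sigma_k^-1 - sigma_k^-1]

    The probability blocks depend on ``transition_grad``:

    * ``'softmax'`` (default): gradients with respect to the natural
      (softmax-logit) parameters of pi and the rows of A — the classical
      Fisher-score form for HMM transition parameters:
      g_pi = gamma_1 - pi (per session, summed),
      g_A_jk = sum_t xi_t(j,k) - A_jk sum_t,k' xi_t(j,k').
      These stay on the occupancy scale, so rare transitions do not blow up
      the score.
    * ``'probability'``: raw gradients on the probability scale,
      g_pi_k = gamma_1(k)/pi_k and g_A_jk = sum_t xi_t(j,k)/A_jk, with
      entries below 1e-12 floored before division; ``tangent`` additionally
      row-mean-centres them (projection onto the simplex tangent).

    ``scale_by_T`` divides the whole score by the timepoint count.

    Returns (gradient vector, block_index).
    """
    x = np.asarray(x, dtype=float)
    K, M = group.K, group.M
    post = forward_backward(group, x, lengths=lengths)

    n_sessions = post.session_gamma0.shape[0]
    g0 = post.session_gamma0.sum(axis=0)
    xi_sum = post.xi.sum(axis=0)
    if transition_grad == "softmax":
        g_pi = g0 - n_sessions * group.pi
        g_A = xi_sum - group.A * xi_sum.sum(axis=1, keepdims=True)
    elif transition_grad == "probability":
        g_pi = g0 / np.maximum(group.pi, _PROB_FLOOR)
        g_A = xi_sum / np.maximum(group.A, _PROB_FLOOR)
        if np.any(group.pi < _PROB_FLOOR) or np.any(group.A < _PROB_FLOOR):
            logger.warning("probability entries below floor encountered in fisher_score")
        if tangent:
            g_pi = g_pi - g_pi.mean()
            g_A = g_A - g_A.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown transition_grad {transition_grad!r}")

    g_mu = np.empty((K, M))
    g_sigma = np.empty((K, M, M))
    for k in range(K):
        Sinv = np.linalg.inv(group.sigma[k])
        d = x - group.mu[k]
        w = post.gamma[:, k]
        g_mu[k] = Sinv @ (w @ d)
        # sum_t w_t d_t d_t^T, whitened on both sides
        S_w = (w[:, None] * d).T @ d
        g_sigma[k] = 0.5 * (Sinv @ S_w @ Sinv - w.sum() * Sinv)

    vec = np.concatenate([g_pi, g_A.ravel(), g_mu.ravel(), g_sigma.ravel()])
    if scale_by_T:
        vec = vec / x.shape[0]
    return vec, _block_index(K, M)


def fisher_scores(group: HMMParams, series, lengths=None, **kwargs) -> FeatureSet:
    """Fisher scores for a list of subjects, as an N x D FeatureSet."""
    if lengths is None:
        lengths = [None] * len(series)
    rows, bi = [], None
    for x, ln in zip(series, lengths):
        v, bi = fisher_score(group, x, lengths=ln, **kwargs)
        rows.append(v)
    return FeatureSet(np.vstack(rows), bi)


# ---------------------------------------------------------------------------
# feature subsets
# ---------------------------------------------------------------------------

_STATE_BLOCKS = ("mu", "sigma")
_TRANSITION_BLOCKS = ("pi", "A")


def _columns(features: FeatureSet, blocks) -> np.ndarray:
    idx = []
    for b in blocks:
        if b in features.block_index:
            sl = features.block_index[b]
            idx.extend(range(sl.start, sl.stop))
    return np.asarray(idx, dtype=int)


def subset_features(features: FeatureSet, mode: str, *, train_rows=None,
                    n_components=None, random_state=None) -> FeatureSet:
    """Restrict a feature set to state or transition blocks, or PCA-reduce.

    mode='state_only' keeps mu and sigma; 'transition_only' keeps pi and A;
    'pca_state' keeps all transition columns and replaces the state block by
    its leading principal components (as many as there are transition
    features by default, e.g. 42 for K=6), fit on ``train_rows``.
    """
    X = features.values
    tcols = _columns(features, _TRANSITION_BLOCKS)
    scols = _columns(features, _STATE_BLOCKS)
    if mode == "state_only":
        bi, start = {}, 0
        for b in _STATE_BLOCKS:
            sl = features.block_index[b]
            width = sl.stop - sl.start
            bi[b] = slice(start, start + width)
            start += width
        return FeatureSet(X[:, scols], bi, features.normalised)
    if mode == "transition_only":
        bi, start = {}, 0
        for b in _TRANSITION_BLOCKS:
            sl = features.block_index[b]
            width = sl.stop - sl.start
            bi[b] = slice(start, start + width)
            start += width
        return FeatureSet(X[:, tcols], bi, features.normalised)
    if mode == "pca_state":
        n_comp = int(n_components) if n_components is not None else tcols.size
        rows = np.arange(X.shape[0]) if train_rows is None else np.asarray(train_rows)
        if rows.size < n_comp:
            raise ValueError(f"PCA with {n_comp} components needs >= {n_comp} subjects, got {rows.size}")
        pca = PCA(n_components=n_comp, random_state=random_state)
        pca.fit(X[rows][:, scols])
        Z = pca.transform(X[:, scols])
        out = np.hstack([X[:, tcols], Z])
        bi, start = {}, 0
        for b in _TRANSITION_BLOCKS:
            sl = features.block_index[b]
            width = sl.stop - sl.start
            bi[b] = slice(start, start + width)
            start += width
        bi["pca_state"] = slice(start, start + n_comp)
        return FeatureSet(out, bi, features.normalised)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def linear_kernel(features) -> np.ndarray:
    """Gram matrix of inner products between subjects' feature vectors."""
    X = features.values if isinstance(features, FeatureSet) else np.asarray(features)
    K = X @ X.T
    return 0.5 * (K + K.T)


def _pairwise_dist(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D2, 0.0, out=D2)
    return np.sqrt(D2)


def effective_tau(dist: np.ndarray, tau: float, relative: bool, train_rows=None) -> float:
    """Resolve the radial-basis width: literal, or tau x median training distance."""
    if not relative:
        return float(tau)
    rows = np.arange(dist.shape[0]) if train_rows is None else np.asarray(train_rows)
    sub = dist[np.ix_(rows, rows)]
    off = sub[np.triu_indices_from(sub, k=1)]
    med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
    return float(tau) * med


def gaussian_kernel(features, tau: float, *, relative: bool = True, train_rows=None) -> np.ndarray:
    """Radial-basis kernel exp(-||f_n - f_m||^2 / (2 tau_eff^2))."""
    if tau is None:
        raise ValueError("gaussian kernel requires tau")
    X = features.values if isinstance(features, FeatureSet) else np.asarray(features)
    D = _pairwise_dist(X)
    t = effective_tau(D, tau, relative, train_rows)
    return np.exp(-(D**2) / (2.0 * t**2))


def naive_kernel(features: FeatureSet, kind: str = "linear", tau=None, **kwargs) -> np.ndarray:
    """Kernel on (optionally normalised) vectorised subject parameters."""
    if kind == "linear":
        return linear_kernel(features)
    if kind == "gaussian":
        if tau is None:
            raise ValueError("gaussian kernel requires tau")
        return gaussian_kernel(features, tau, **kwargs)
    raise ValueError(f"unknown kind {kind!r}")


def whiten_scores(scores: FeatureSet, ridge: float = 1e-10) -> FeatureSet:
    """Whiten Fisher scores by the empirical Fisher information.

    F_hat = (1/N) sum_n g_n g_n^T is the second-moment matrix of the scores;
    whitening implements the invariant Fisher kernel g^T F^-1 g.  Uses the
    eigendecomposition in the N-dimensional span for D >> N.
    """
    X = scores.values
    N = X.shape[0]
    if N < 2:
        raise ValueError("whitening requires at least 2 subjects")
    # F = X^T X / N shares nonzero eigenvalues with G = X X^T / N
    G = X @ X.T / N
    w, V = np.linalg.eigh(G)
    keep = w > ridge * w.max()
    w, V = w[keep], V[:, keep]
    # X F^{-1/2} computed in the span of the scores: equals sqrt(N) U W^T
    # for X = U S W^T, so the whitened Gram matrix has trace N * rank(F)
    Z = (V / np.sqrt(w)) @ (V.T @ X)
    return replace(scores, values=Z)


def fisher_kernel(scores: FeatureSet, kind: str = "linear", tau=None,
                  whiten: bool = False, **kwargs) -> np.ndarray:
    """Practical Fisher kernel: inner products (or RBF) of Fisher scores.

    ``whiten`` applies the empirical Fisher-information whitening first
    (the invariant Fisher kernel); off by default.
    """
    fs = whiten_scores(scores) if whiten else scores
    return naive_kernel(fs, kind=kind, tau=tau, **kwargs)


# ---------------------------------------------------------------------------
# KL divergence between HMMs
# ---------------------------------------------------------------------------


def _categorical_kl(p: np.ndarray, q: np.ndarray) -> float:
    p = np.maximum(p, _PROB_FLOOR)
    q = np.maximum(q, _PROB_FLOOR)
    return float(np.sum(p * (np.log(p) - np.log(q))))


def kl_hmm(n: HMMParams, m: HMMParams) -> float:
    """Approximate KL(HMM_n || HMM_m) for state-aligned HMMs.

    sum_k nu_k [ KL(A_k^n || A_k^m) + KL(G_k^n || G_k^m) ] where nu is the
    stationary distribution of the first model's transition matrix, the
    transition rows use the categorical closed form on point estimates, and
    the state Gaussians use the multivariate-normal closed form.
    """
    if n.K != m.K or n.M != m.M:
        raise ValueError("HMMs must share K and M")
    nu = n.stationary_dist
    total = 0.0
    for k in range(n.K):
        total += nu[k] * _categorical_kl(n.A[k], m.A[k])
        total += nu[k] * gaussian_kl(n.mu[k], n.sigma[k], m.mu[k], m.sigma[k])
    return float(total)


def kl_kernel(subject_params, tau: float = 1.0, *, relative: bool = True, train_rows=None):
    """Symmetrised KL divergence matrix and its radial-basis kernel.

    D(n,m) = 0.5 KL(n||m) + 0.5 KL(m||n), then
    kappa(n,m) = exp(-D(n,m)^2 / (2 tau_eff^2)).

    Returns (divergence matrix, kernel matrix).
    """
    N = len(subject_params)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            d = 0.5 * kl_hmm(subject_params[i], subject_params[j]) \
                + 0.5 * kl_hmm(subject_params[j], subject_params[i])
            D[i, j] = D[j, i] = d
    t = effective_tau(D, tau, relative, train_rows)
    K = np.exp(-(D**2) / (2.0 * t**2))
    return D, K


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class FisherScores(BaseEstimator, TransformerMixin):
    """Transformer: list of subject timeseries -> Fisher-score matrix.

    Fits the group HMM on the training subjects (or accepts a prefitted
    model via ``group_model``) and emits one gradient row per subject.
    """

    def __init__(self, n_states=6, group_model=None, zero_mean=False,
                 transition_grad="softmax", tangent=False, scale_by_T=False,
                 random_state=None, **hmm_kwargs):
        self.n_states = n_states
        self.group_model = group_model
        self.zero_mean = zero_mean
        self.transition_grad = transition_grad
        self.tangent = tangent
        self.scale_by_T = scale_by_T
        self.random_state = random_state
        self.hmm_kwargs = hmm_kwargs

    def fit(self, X, y=None):
        if self.group_model is not None:
            self.group_ = self.group_model
        else:
            from .hmm import fit_group_hmm

            self.group_, _ = fit_group_hmm(
                list(X), self.n_states, zero_mean=self.zero_mean,
                random_state=self.random_state, **self.hmm_kwargs,
            )
        return self

    def transform(self, X) -> np.ndarray:
        fs = fisher_scores(self.group_, list(X), transition_grad=self.transition_grad,
                           tangent=self.tangent, scale_by_T=self.scale_by_T)
        self.block_index_ = fs.block_index
        return fs.values


class NaiveParameterVectors(BaseEstimator, TransformerMixin):
    """Transformer: list of timeseries -> dual-estimated parameter vectors."""

    def __init__(self, n_states=6, group_model=None, zero_mean=False,
                 normalise=False, random_state=None, **hmm_kwargs):
        self.n_states = n_states
        self.group_model = group_model
        self.zero_mean = zero_mean
        self.normalise = normalise
        self.random_state = random_state
        self.hmm_kwargs = hmm_kwargs

    def fit(self, X, y=None):
        if self.group_model is not None:
            self.group_ = self.group_model
        else:
            from .hmm import fit_group_hmm

            self.group_, _ = fit_group_hmm(
                list(X), self.n_states, zero_mean=self.zero_mean,
                random_state=self.random_state, **self.hmm_kwargs,
            )
        return self

    def transform(self, X) -> np.ndarray:
        from .hmm import dual_estimate

        params = [dual_estimate(self.group_, x, zero_mean=self.zero_mean) for x in X]
        fs = naive_features(params)
        if self.normalise:
            fs = normalise_features(fs)
        self.block_index_ = fs.block_index
        return fs.values
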