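"""Gaussian-observation hidden Markov models for multi-subject timeseries.

A group-level HMM is fit to the concatenated, per-channel z-scored
timeseries of all subjects by maximum-a-posteriori EM (Baum-Welch with an
additive diagonal covariance regulariser).  Subject-level models are then
obtained by *dual estimation*: a short EM run on a single subject's data
initialised at the group optimum, which preserves state identities.

States are multivariate Gaussians, so each state is a pattern of amplitude
(its mean) and functional connectivity (its covariance).  A zero-mean
variant pins all state means to zero, leaving only covariance to vary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "PosteriorStats",
    "GaussianHMMEstimator",
    "normalise_timeseries",
    "fit_group_hmm",
    "forward_backward",
    "log_likelihood",
    "dual_estimate",
    "sample_hmm",
]


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    """Point parameters theta = [pi, A, mu, sigma] of a K-state Gaussian HMM.

    Attributes
    ----------
    pi : (K,) initial state probabilities.
    A : (K, K) row-stochastic transition matrix.
    mu : (K, M) state means (all zero under the zero-mean variant).
    sigma : (K, M, M) symmetric positive-definite state covariances.
    """

    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.mu.shape[1]

    @property
    def n_parameters(self) -> int:
        K, M = self.K, self.M
        return K + K * K + K * M + K * M * M

    @property
    def stationary_dist(self) -> np.ndarray:
        """Stationary distribution nu solving nu = nu A."""
        w, v = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        nu = np.real(v[:, i])
        nu = np.abs(nu)
        return nu / nu.sum()

    def validate(self, atol: float = 1e-8) -> None:
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("pi does not sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of A do not sum to 1")
        if self.mu.shape != (self.K, self.M):
            raise ValueError("mu has wrong shape")
        if self.sigma.shape != (self.K, self.M, self.M):
            raise ValueError("sigma has wrong shape")
        for k in range(self.K):
            S = self.sigma[k]
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"sigma[{k}] is not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"sigma[{k}] is not positive definite")
        nu = self.stationary_dist
        if not np.allclose(nu @ self.A, nu, atol=atol):
            raise ValueError("stationary distribution inconsistent with A")

    def copy(self) -> "HMMParams":
        return HMMParams(self.pi.copy(), self.A.copy(), self.mu.copy(), self.sigma.copy())


@dataclass
class PosteriorStats:
    """Forward-backward output for one subject.

    gamma is T x K (state posteriors), xi stacks the pairwise posteriors of
    every within-session transition, so its first axis has length
    T - n_sessions.  session_gamma0 holds gamma at the first timepoint of
    each session (needed for the pi gradient and pi re-estimation).
    """

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float
    session_gamma0: np.ndarray = field(default=None)  # (S, K)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def normalise_timeseries(x: np.ndarray) -> np.ndarray:
    """Z-score each channel (population-SD convention).

    Raises
    ------
    ValueError
        If any channel is constant, naming the offending column.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("timeseries must be a T x M matrix with T >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("timeseries contains non-finite values")
    sd = x.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant channel(s) at column index {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# forward-backward (scaled), numba-accelerated where available
# ---------------------------------------------------------------------------


def _fb_core(pi, A, B):
    """Scaled forward-backward for one chain.

    B is the T x K matrix of (shifted) emission likelihoods; returns
    gamma (T,K), xi (T-1,K,K) and the log-likelihood *up to* the additive
    shift removed from B by the caller.
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = np.empty(K)
        for k in range(K):
            s = 0.0
            for j in range(K):
                s += alpha[t - 1, j] * A[j, k]
            a[k] = s * B[t, k]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            s = 0.0
            for k in range(K):
                s += A[j, k] * B[t + 1, k] * beta[t + 1, k]
            beta[t, j] = s / c[t + 1]

    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()

    xi = np.empty((T - 1, K, K))
    for t in range(T - 1):
        tot = 0.0
        for j in range(K):
            for k in range(K):
                v = alpha[t, j] * A[j, k] * B[t + 1, k] * beta[t + 1, k]
                xi[t, j, k] = v
                tot += v
        xi[t] /= tot

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return gamma, xi, loglik


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fb_core = njit(cache=True)(_fb_core)
except ImportError:  # pragma: no cover
    pass


def _emission_logprob(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """T x K log N(x_t | mu_k, sigma_k); raises naming a singular state."""
    T, M = x.shape
    K = params.K
    logB = np.empty((T, K))
    for k in range(K):
        try:
            L = linalg.cholesky(params.sigma[k], lower=True)
        except linalg.LinAlgError as e:
            raise ValueError(f"sigma for state {k} is singular or not SPD") from e
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        sol = linalg.solve_triangular(L, (x - params.mu[k]).T, lower=True)
        quad = np.einsum("ij,ij->j", sol, sol)
        logB[:, k] = -0.5 * (M * np.log(2.0 * np.pi) + logdet + quad)
    return logB


def _session_slices(T: int, lengths) -> list[slice]:
    if lengths is None:
        return [slice(0, T)]
    lengths = list(lengths)
    if sum(lengths) != T:
        raise ValueError("session lengths do not sum to the number of timepoints")
    out, start = [], 0
    for ln in lengths:
        out.append(slice(start, start + ln))
        start += ln
    return out


def forward_backward(params: HMMParams, x: np.ndarray, lengths=None) -> PosteriorStats:
    """State posteriors gamma, pairwise posteriors xi and the log-likelihood.

    Uses the scaled recursions, stable for long timeseries.  With multiple
    sessions (``lengths``) each session is an independent chain restarting
    from pi; xi excludes the between-session joins.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != params.M:
        raise ValueError("channel count does not match the model")
    logB = _emission_logprob(x, params)
    slices = _session_slices(x.shape[0], lengths)

    gammas, xis, g0 = [], [], []
    loglik = 0.0
    for sl in slices:
        lb = logB[sl]
        shift = lb.max(axis=1)
        B = np.exp(lb - shift[:, None])
        g, xi, ll = _fb_core(params.pi, params.A, B)
        loglik += ll + shift.sum()
        gammas.append(g)
        xis.append(xi)
        g0.append(g[0])
    return PosteriorStats(
        gamma=np.vstack(gammas),
        xi=np.concatenate(xis, axis=0) if xis else np.empty((0, params.K, params.K)),
        loglik=float(loglik),
        session_gamma0=np.vstack(g0),
    )


def log_likelihood(params: HMMParams, x: np.ndarray, lengths=None) -> float:
    """log P(x | theta), a thin wrapper over :func:`forward_backward`."""
    return forward_backward(params, x, lengths=lengths).loglik


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def _m_step(data, posts, slices_per_series, zero_mean, cov_reg, pi_smoothing=1e-3):
    K = posts[0].gamma.shape[1]
    M = data[0].shape[1]

    # pi from first timepoints of every session
    g0 = np.vstack([p.session_gamma0 for p in posts])
    pi = g0.mean(axis=0) + pi_smoothing
    pi /= pi.sum()

    xi_sum = np.zeros((K, K))
    for p in posts:
        xi_sum += p.xi.sum(axis=0)
    A = xi_sum / xi_sum.sum(axis=1, keepdims=True)

    Nk = np.zeros(K)
    sx = np.zeros((K, M))
    for x, p in zip(data, posts):
        Nk += p.gamma.sum(axis=0)
        sx += p.gamma.T @ x
    mu = np.zeros((K, M)) if zero_mean else sx / Nk[:, None]

    sigma = np.zeros((K, M, M))
    for x, p in zip(data, posts):
        for k in range(K):
            d = x - mu[k]
            sigma[k] += (p.gamma[:, k, None] * d).T @ d
    for k in range(K):
        sigma[k] /= Nk[k]
        sigma[k] = 0.5 * (sigma[k] + sigma[k].T)
        reg = cov_reg * np.trace(sigma[k]) / M
        sigma[k][np.diag_indices(M)] += reg
    return HMMParams(pi, A, mu, sigma), Nk


def _init_params(data, K, zero_mean, cov_reg, rng) -> HMMParams:
    """K-means state means, pooled covariance, uniform pi, sticky A."""
    X = np.vstack(data)
    M = X.shape[1]
    pooled = np.cov(X.T, bias=True).reshape(M, M)
    if K == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        mu = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
        # subsample for speed on long recordings
        idx = rng.choice(X.shape[0], size=min(X.shape[0], 20000), replace=False)
        km.fit(X[idx])
        mu = km.cluster_centers_
        labels = None
    if zero_mean:
        mu = np.zeros((K, M))
        # jitter covariance scales to break state symmetry
        scales = 1.0 + 0.1 * rng.standard_normal(K)
        sigma = np.stack([pooled * abs(s) for s in scales])
    else:
        sigma = np.stack([pooled.copy() for _ in range(K)])
    for k in range(K):
        sigma[k][np.diag_indices(M)] += cov_reg * np.trace(sigma[k]) / M + 1e-8
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    A /= A.sum(axis=1, keepdims=True)
    return HMMParams(pi, A, np.asarray(mu, dtype=float), sigma)


def _em(data, slices, params, max_iter, tol, zero_mean, cov_reg, min_occupancy=0.0,
        anchor: HMMParams | None = None):
    """MAP-EM loop; returns (params, loglik history).

    ``anchor`` supplies fallback parameters for states whose total posterior
    occupancy drops below ``min_occupancy`` (used by dual estimation).
    """
    history = []
    for _ in range(max_iter):
        posts = [forward_backward(params, x, lengths=ln) for x, ln in zip(data, slices)]
        ll = sum(p.loglik for p in posts)
        history.append(ll)
        new, Nk = _m_step(data, posts, slices, zero_mean, cov_reg)
        if anchor is not None:
            low = Nk < min_occupancy
            for k in np.where(low)[0]:
                logger.info("state %d occupancy %.3g below threshold; keeping anchor values", k, Nk[k])
                new.mu[k] = anchor.mu[k]
                new.sigma[k] = anchor.sigma[k]
        params = new
        if len(history) > 1:
            prev = history[-2]
            if abs(history[-1] - prev) < tol * abs(prev):
                break
    return params, history


def fit_group_hmm(
    series,
    K: int,
    *,
    lengths=None,
    zero_mean: bool = False,
    cov_reg: float = 1e-5,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    random_state=None,
):
    """Fit a group-level K-state Gaussian HMM to a list of subjects' timeseries.

    Each subject's array is treated as one chain (or several, via
    ``lengths``: a per-subject list of session lengths).  Estimation is
    MAP-EM: Baum-Welch with an additive diagonal covariance regulariser of
    ``cov_reg * trace(sigma_k)/M`` per state.  Multiple restarts differ in
    their k-means initialisation; the best final log-likelihood wins.

    Returns
    -------
    (HMMParams, loglik_history) of the winning restart.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    data = [np.asarray(x, dtype=float) for x in series]
    M = data[0].shape[1]
    if any(x.shape[1] != M for x in data):
        raise ValueError("all subjects must share the same channel count")
    if any(not np.all(np.isfinite(x)) for x in data):
        raise ValueError("input contains non-finite values")
    total_T = sum(x.shape[0] for x in data)
    if total_T < K * (M + 1):
        raise ValueError(f"K={K} too large for {total_T} total timepoints with M={M}")
    if lengths is None:
        lengths = [None] * len(data)

    rng = np.random.default_rng(random_state)
    best, best_hist = None, None
    for _ in range(max(1, n_restarts)):
        init = _init_params(data, K, zero_mean, cov_reg, rng)
        params, hist = _em(data, lengths, init, max_iter, tol, zero_mean, cov_reg)
        if best_hist is None or hist[-1] > best_hist[-1]:
            best, best_hist = params, hist
    return best, best_hist


def dual_estimate(
    group: HMMParams,
    x: np.ndarray,
    *,
    lengths=None,
    max_iter: int = 10,
    tol: float = 1e-5,
    zero_mean: bool = False,
    cov_reg: float = 1e-5,
    min_occupancy: float = 1.0,
) -> HMMParams:
    """Subject-level parameters: EM on one subject initialised at the group model.

    The short schedule keeps the subject model anchored to the group optimum,
    which preserves state identity (no relabelling).  States with total
    posterior occupancy below ``min_occupancy`` timepoints keep the group
    values for their Gaussian.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != group.M:
        raise ValueError("channel count does not match the group model")
    params, _ = _em(
        [x], [lengths], group.copy(), max_iter, tol, zero_mean, cov_reg,
        min_occupancy=min_occupancy, anchor=group,
    )
    return params


def sample_hmm(params: HMMParams, T: int, rng=None, lengths=None):
    """Sample a timeseries and its state sequence from an HMM.

    States follow q_1 ~ Cat(pi), q_t | q_{t-1}=k ~ Cat(A_k); observations
    x_t | q_t=k ~ N(mu_k, sigma_k).  ``lengths`` restarts the chain at pi
    for each session.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(rng)
    K, M = params.K, params.M
    chols = [np.linalg.cholesky(params.sigma[k]) for k in range(K)]
    states = np.empty(T, dtype=int)
    X = np.empty((T, M))
    for sl in _session_slices(T, lengths):
        prev = None
        for t in range(sl.start, sl.stop):
            p = params.pi if prev is None else params.A[prev]
            s = int(rng.choice(K, p=p))
            states[t] = s
            X[t] = params.mu[s] + chols[s] @ rng.standard_normal(M)
            prev = s
    return X, states


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class GaussianHMMEstimator(BaseEstimator):
    """Group-level Gaussian HMM with dual estimation, sklearn-style.

    Parameters
    ----------
    n_states : number of hidden states K.
    zero_mean : pin all state means to zero (covariance-only states).
    cov_reg : diagonal covariance regulariser, as a fraction of trace/M.
    n_restarts : k-means initialisations tried; best log-likelihood kept.
    max_iter, tol : EM schedule.
    random_state : seed for initialisation.

    Attributes
    ----------
    params_ : fitted :class:`HMMParams`.
    loglik_ : final training log-likelihood.
    history_ : per-iteration log-likelihoods of the winning restart.
    """

    def __init__(self, n_states=6, zero_mean=False, cov_reg=1e-5, n_restarts=3,
                 max_iter=500, tol=1e-6, random_state=None):
        self.n_states = n_states
        self.zero_mean = zero_mean
        self.cov_reg = cov_reg
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, lengths=None):
        """Fit to a list of (T, M) subject timeseries (or a single array)."""
        series = [X] if isinstance(X, np.ndarray) and X.ndim == 2 else list(X)
        self.params_, self.history_ = fit_group_hmm(
            series, self.n_states, lengths=lengths, zero_mean=self.zero_mean,
            cov_reg=self.cov_reg, n_restarts=self.n_restarts,
            max_iter=self.max_iter, tol=self.tol, random_state=self.random_state,
        )
        self.loglik_ = self.history_[-1]
        return self

    def score(self, X, lengths=None) -> float:
        return log_likelihood(self.params_, X, lengths=lengths)

    def posteriors(self, X, lengths=None) -> PosteriorStats:
        return forward_backward(self.params_, X, lengths=lengths)

    def dual_estimate(self, X, lengths=None, **kwargs) -> HMMParams:
        kwargs.setdefault("zero_mean", self.zero_mean)
        kwargs.setdefault("cov_reg", self.cov_reg)
        return dual_estimate(self.params_, X, lengths=lengths, **kwargs)

    def sample(self, T: int, random_state=None, lengths=None):
        return sample_hmm(self.params_, T, rng=random_state, lengths=lengths)
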