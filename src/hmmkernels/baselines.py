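"""Time-averaged functional-connectivity baselines.

Prediction methods that ignore temporal dynamics: each subject is reduced
to the covariance of their (z-scored) timeseries, and similarity or
features are derived from those SPD matrices — a symmetrised-Gaussian-KL
kernel, a log-Euclidean kernel, plain ridge on the unwrapped covariances,
and ridge on tangent-space projections at the Frechet mean (the Riemannian
variant).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import ledoit_wolf

__all__ = [
    "time_averaged_cov",
    "gaussian_kl",
    "logm_spd",
    "log_euclidean_distance",
    "log_euclidean_kernel",
    "frechet_mean",
    "tangent_project",
    "time_averaged_kl_kernel",
    "TangentSpace",
    "ridge_on_features",
]


def _check_spd(S: np.ndarray, name: str = "matrix") -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError(f"{name} is not positive definite")
    return S


def time_averaged_cov(x: np.ndarray, shrinkage="auto") -> np.ndarray:
    """Per-subject time-averaged FC: the sample covariance across timepoints.

    shrinkage='auto' uses Ledoit-Wolf analytic shrinkage toward a scaled
    identity; a float in [0, 1] fixes the shrinkage intensity; None returns
    the raw sample covariance (then falls back to a small diagonal load if
    rank-deficient).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("timeseries contains non-finite values")
    M = x.shape[1]
    if shrinkage == "auto":
        C, _ = ledoit_wolf(x, assume_centered=False)
    else:
        C = np.cov(x.T, bias=True).reshape(M, M)
        if shrinkage:
            t = np.trace(C) / M
            C = (1 - shrinkage) * C + shrinkage * t * np.eye(M)
    C = 0.5 * (C + C.T)
    if np.linalg.eigvalsh(C).min() <= 1e-12 * np.trace(C) / M:
        C[np.diag_indices(M)] += 1e-6 * np.trace(C) / M
    return C


def gaussian_kl(mu1, S1, mu2, S2) -> float:
    """KL( N(mu1, S1) || N(mu2, S2) ), multivariate normal closed form."""
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    S1 = np.atleast_2d(np.asarray(S1, dtype=float))
    S2 = np.atleast_2d(np.asarray(S2, dtype=float))
    M = mu1.shape[0]
    _check_spd(S1, "S1")
    _check_spd(S2, "S2")
    L2 = linalg.cholesky(S2, lower=True)
    solve = linalg.cho_solve((L2, True), np.eye(M))
    d = mu2 - mu1
    logdet1 = np.linalg.slogdet(S1)[1]
    logdet2 = 2.0 * np.sum(np.log(np.diag(L2)))
    return float(0.5 * (np.trace(solve @ S1) + d @ solve @ d - M + logdet2 - logdet1))


def logm_spd(S: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition."""
    w, V = np.linalg.eigh(S)
    if w.min() <= 0:
        raise ValueError("matrix logarithm requires a positive definite matrix")
    return (V * np.log(w)) @ V.T


def _powm_spd(S: np.ndarray, p: float) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    return (V * w**p) @ V.T


def log_euclidean_distance(C1: np.ndarray, C2: np.ndarray) -> float:
    """Frobenius norm of logm(C1) - logm(C2)."""
    return float(np.linalg.norm(logm_spd(C1) - logm_spd(C2), "fro"))


def log_euclidean_kernel(covs, tau: float = 1.0, *, relative: bool = True, train_rows=None):
    """Gaussian kernel on pairwise log-Euclidean distances.

    Returns (distance matrix, kernel matrix).  tau is a multiplier of the
    median training-set distance unless ``relative=False``.
    """
    from .kernels import effective_tau

    logs = []
    for i, C in enumerate(covs):
        try:
            logs.append(logm_spd(C))
        except ValueError as e:
            raise ValueError(f"matrix logarithm failed for subject {i}") from e
    N = len(logs)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            D[i, j] = D[j, i] = np.linalg.norm(logs[i] - logs[j], "fro")
    t = effective_tau(D, tau, relative, train_rows)
    return D, np.exp(-(D**2) / (2.0 * t**2))


def frechet_mean(covs, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Affine-invariant Frechet (geometric) mean of SPD matrices.

    Fixed-point iteration R <- R^{1/2} exp( mean_i log(R^{-1/2} C_i R^{-1/2}) ) R^{1/2}.
    """
    covs = [np.asarray(C, dtype=float) for C in covs]
    R = np.mean(covs, axis=0)
    for _ in range(max_iter):
        Rh = _powm_spd(R, 0.5)
        Rih = _powm_spd(R, -0.5)
        T = np.mean([logm_spd(Rih @ C @ Rih) for C in covs], axis=0)
        T = 0.5 * (T + T.T)
        if np.linalg.norm(T, "fro") < tol:
            return R
        w, V = np.linalg.eigh(T)
        expT = (V * np.exp(w)) @ V.T
        R = Rh @ expT @ Rh
        R = 0.5 * (R + R.T)
    raise RuntimeError(f"Frechet mean did not converge in {max_iter} iterations")


def _vec_triu(S: np.ndarray) -> np.ndarray:
    """Upper-triangle vectorisation with sqrt(2) off-diagonal weighting.

    Preserves the Frobenius norm of symmetric matrices, so Euclidean
    geometry on the vectors matches the tangent-space metric.
    """
    M = S.shape[0]
    i, j = np.triu_indices(M)
    w = np.where(i == j, 1.0, np.sqrt(2.0))
    return S[i, j] * w


def tangent_project(covs, reference=None, train_rows=None) -> np.ndarray:
    """Project SPD covariances to the tangent space at a reference point.

    Each C becomes vec( logm( R^{-1/2} C R^{-1/2} ) ); R defaults to the
    affine-invariant Frechet mean of the training subjects' covariances.
    Output is N x M(M+1)/2.
    """
    covs = [np.asarray(C, dtype=float) for C in covs]
    if reference is None:
        rows = range(len(covs)) if train_rows is None else train_rows
        reference = frechet_mean([covs[i] for i in rows])
    Rih = _powm_spd(np.asarray(reference, dtype=float), -0.5)
    out = [_vec_triu(logm_spd(Rih @ C @ Rih)) for C in covs]
    return np.vstack(out)


def time_averaged_kl_kernel(covs, tau: float = 1.0, *, relative: bool = True, train_rows=None):
    """Symmetrised Gaussian-KL kernel on time-averaged covariances.

    Means are fixed at zero (channels are z-scored), mirroring the HMM KL
    kernel's radial-basis embedding.  Returns (divergence, kernel).
    """
    from .kernels import effective_tau

    N = len(covs)
    zero = [np.zeros(np.asarray(C).shape[0]) for C in covs]
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            d = 0.5 * gaussian_kl(zero[i], covs[i], zero[j], covs[j]) \
                + 0.5 * gaussian_kl(zero[j], covs[j], zero[i], covs[i])
            D[i, j] = D[j, i] = d
    t = effective_tau(D, tau, relative, train_rows)
    return D, np.exp(-(D**2) / (2.0 * t**2))


class TangentSpace(BaseEstimator, TransformerMixin):
    """Transformer: list/stack of SPD matrices -> tangent-space vectors.

    The reference (Frechet mean) is estimated in ``fit`` from the training
    covariances only, so the transform is leakage-safe inside CV pipelines.
    """

    def __init__(self, tol=1e-8, max_iter=200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.reference_ = frechet_mean(list(X), tol=self.tol, max_iter=self.max_iter)
        return self

    def transform(self, X) -> np.ndarray:
        return tangent_project(list(X), reference=self.reference_)


def ridge_on_features(features, y, confounds, scheme, grid, variable_name="y"):
    """Nested-CV ridge regression directly on features (with intercept).

    Centring features and target with training-fold statistics makes this
    the primal equivalent of kernel ridge with a linear kernel on centred
    features.  Reuses the prediction module's CV machinery and metrics.
    """
    from .prediction import nested_cv_predict_features

    return nested_cv_predict_features(np.asarray(features, dtype=float), y,
                                      confounds, scheme, grid,
                                      variable_name=variable_name)
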