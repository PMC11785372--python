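"""Kernel ridge regression with family-aware nested cross-validation.

The predictor is kernel ridge regression (KRR): weights alpha solve
(kappa + lambda I) alpha = y on the training block of a kernel matrix, and
test predictions are h alpha for the test x train block.  Model selection
(the ridge penalty lambda, and the radial-basis width tau for Gaussian
kernels) uses an inner grid-search loop; the outer loop scores the refit
model.  Folds are group-aware so that subjects sharing a family ID are
never split across training and test.

Targets are deconfounded inside the CV: confound regression coefficients
are estimated on the training fold only and applied to the test fold.
Accuracy (Pearson r, R^2) is reported in deconfounded space; maximum
absolute errors (MAXAE, and NMAXAE = MAXAE / target range) in original
space, with the confound model's prediction added back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HyperparamGrid",
    "CVScheme",
    "KRRModel",
    "KernelRidgePredictor",
    "PredictionResult",
    "make_cv_scheme",
    "krr_fit",
    "krr_predict",
    "deconfound",
    "evaluate",
    "nested_cv_predict",
    "nested_cv_predict_features",
    "corrected_rkcv_ttest",
    "bh_fdr",
]

#: ridge penalties searched in the inner loop
DEFAULT_LAMBDAS = (0.0001, 0.001, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
#: radial-basis widths searched for Gaussian kernels
DEFAULT_TAUS = (1 / 5, 1 / 3, 1 / 2, 1.0, 2.0, 3.0, 5.0)


@dataclass
class HyperparamGrid:
    """Grid searched by the inner CV loop; all values must be positive."""

    lambdas: tuple = DEFAULT_LAMBDAS
    taus: tuple = DEFAULT_TAUS

    def __post_init__(self):
        if any(l <= 0 for l in self.lambdas) or any(t <= 0 for t in self.taus):
            raise ValueError("grid values must be positive")


@dataclass
class CVScheme:
    """Family-aware fold assignments, reused across all compared methods.

    outer[rep] is a list of (train, test) index arrays; inner[rep][fold] is
    a list of (train, val) arrays expressed in absolute subject indices
    (subsets of the corresponding outer training set).
    """

    outer: list
    inner: list
    groups: np.ndarray
    seed: int
    k_outer: int
    k_inner: int

    @property
    def n_repeats(self) -> int:
        return len(self.outer)


def _group_kfold(idx: np.ndarray, groups: np.ndarray, k: int, rng) -> list:
    """Randomised group-aware k-fold on a subset of subjects."""
    gk = GroupKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    return [(idx[tr], idx[te]) for tr, te in gk.split(idx, groups=groups[idx])]


def make_cv_scheme(n_subjects=None, groups=None, k_outer: int = 10, k_inner: int = 10,
                   n_repeats: int = 1, seed: int = 0) -> CVScheme:
    """Build randomised, group-aware nested CV folds.

    ``groups`` holds family identifiers (default: every subject its own
    group); members of one group always land in the same fold.  The scheme
    is deterministic under ``seed`` and intended to be shared across all
    methods being compared.
    """
    if groups is None:
        if n_subjects is None:
            raise ValueError("provide n_subjects or groups")
        groups = np.arange(n_subjects)
    groups = np.asarray(groups)
    n = groups.shape[0]
    _, counts = np.unique(groups, return_counts=True)
    if counts.max() > n / k_outer:
        raise ValueError(
            f"largest family ({counts.max()} subjects) exceeds the fold size {n / k_outer:.1f}")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    outer, inner = [], []
    for _ in range(n_repeats):
        folds = _group_kfold(all_idx, groups, k_outer, rng)
        outer.append(folds)
        inner.append([_group_kfold(tr, groups, k_inner, rng) for tr, _ in folds])
    return CVScheme(outer, inner, groups, seed, k_outer, k_inner)


# ---------------------------------------------------------------------------
# kernel ridge regression
# ---------------------------------------------------------------------------


@dataclass
class KRRModel:
    """Fitted KRR weights over the training subjects."""

    alpha: np.ndarray
    lam: float
    training_ids: np.ndarray = field(default=None)


def krr_fit(kernel_train: np.ndarray, y_train: np.ndarray, lam: float,
            training_ids=None) -> KRRModel:
    """Solve (kappa + lambda I) alpha = y by Cholesky factorisation."""
    K = np.asarray(kernel_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    A = K + lam * np.eye(K.shape[0])
    try:
        c, low = linalg.cho_factor(A, lower=True)
        alpha = linalg.cho_solve((c, low), y)
    except linalg.LinAlgError:
        alpha = linalg.solve(A, y, assume_a="sym")
    if not np.all(np.isfinite(alpha)):
        cond = np.linalg.cond(A)
        raise ValueError(f"KRR solve produced non-finite weights (cond ~ {cond:.3g})")
    return KRRModel(alpha=alpha, lam=float(lam), training_ids=training_ids)


def krr_predict(model: KRRModel, kernel_cross: np.ndarray) -> np.ndarray:
    """Predictions y_hat = h alpha for the test x train kernel block."""
    h = np.atleast_2d(np.asarray(kernel_cross, dtype=float))
    if h.shape[1] != model.alpha.shape[0]:
        raise ValueError("cross-kernel column count does not match training size")
    return h @ model.alpha


class KernelRidgePredictor(BaseEstimator, RegressorMixin):
    """Sklearn-style KRR on a precomputed kernel.

    fit(K, y) takes the square training kernel; predict(H) the
    test x train block.
    """

    def __init__(self, lam: float = 0.1):
        self.lam = lam

    def fit(self, X, y):
        self.model_ = krr_fit(X, y, self.lam)
        return self

    def predict(self, X):
        return krr_predict(self.model_, X)


# ---------------------------------------------------------------------------
# deconfounding
# ---------------------------------------------------------------------------


@dataclass
class ConfoundModel:
    """Training-fold linear confound fit (intercept + coefficients)."""

    beta: np.ndarray

    def predict(self, confounds) -> np.ndarray:
        C = _design(confounds)
        return C @ self.beta


def _design(confounds) -> np.ndarray:
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.hstack([np.ones((C.shape[0], 1)), C])


def deconfound(y_train, y_test, confounds_train, confounds_test):
    """Regress confounds out of the target, leakage-safe.

    Coefficients (with intercept) are estimated on the training fold only
    and applied to both folds.  Returns (residual_train, residual_test,
    confound_model); the model maps predictions back to original space.
    """
    Ctr = _design(confounds_train)
    if np.linalg.matrix_rank(Ctr) < Ctr.shape[1]:
        raise ValueError("confound matrix is rank-deficient after adding an intercept")
    beta, *_ = np.linalg.lstsq(Ctr, np.asarray(y_train, dtype=float), rcond=None)
    model = ConfoundModel(beta=beta)
    r_train = np.asarray(y_train, dtype=float) - model.predict(confounds_train)
    r_test = np.asarray(y_test, dtype=float) - model.predict(confounds_test)
    return r_train, r_test, model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray):
    """Pearson r, with zero-variance inputs recorded as r=0 and flagged."""
    if a.std() == 0 or b.std() == 0:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def evaluate(y_true_dc, y_pred_dc, y_true_orig, y_pred_orig, variable_range):
    """Fold-level metrics.

    r and R^2 are computed in deconfounded space; MAXAE and
    NMAXAE = MAXAE / variable_range in original space, where
    ``variable_range`` is the full-sample range of the target.
    """
    y_true_dc = np.asarray(y_true_dc, dtype=float)
    y_pred_dc = np.asarray(y_pred_dc, dtype=float)
    r, degenerate = _pearson(y_pred_dc, y_true_dc)
    ss_res = np.sum((y_true_dc - y_pred_dc) ** 2)
    ss_tot = np.sum((y_true_dc - y_true_dc.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    maxae = float(np.max(np.abs(np.asarray(y_true_orig) - np.asarray(y_pred_orig))))
    return {
        "r": r,
        "R2": float(r2),
        "MAXAE": maxae,
        "NMAXAE": maxae / variable_range,
        "degenerate": degenerate,
    }


@dataclass
class PredictionResult:
    """Tidy per-(variable, repeat, fold) metrics table."""

    table: pd.DataFrame

    def robustness(self) -> pd.Series:
        """S.D. of accuracy r across folds x repeats, per variable."""
        return self.table.groupby("variable")["r"].std(ddof=1)

    def fold_mean(self) -> pd.DataFrame:
        """Accuracies averaged over folds (per variable and repeat)."""
        return self.table.groupby(["variable", "repeat"], as_index=False)["r"].mean()

    def mean_r(self) -> float:
        return float(self.table["r"].mean())


# ---------------------------------------------------------------------------
# nested CV drivers
# ---------------------------------------------------------------------------


def _select_hyperparams(kernels_by_tau, y, confounds, inner_folds, lambdas):
    """Mean inner-fold Pearson r per (lambda, tau); ties go to larger lambda."""
    best, best_score = None, -np.inf
    for tau, Kfull in kernels_by_tau.items():
        for lam in lambdas:
            rs = []
            for tr, va in inner_folds:
                if confounds is not None:
                    y_tr, y_va, _ = deconfound(y[tr], y[va], confounds[tr], confounds[va])
                else:
                    y_tr, y_va = y[tr], y[va]
                model = krr_fit(Kfull[np.ix_(tr, tr)], y_tr, lam)
                pred = krr_predict(model, Kfull[np.ix_(va, tr)])
                r, _ = _pearson(pred, y_va)
                rs.append(r)
            score = float(np.mean(rs))
            if score > best_score or (score == best_score and best is not None
                                      and lam > best[0] and tau == best[1]):
                best, best_score = (lam, tau), score
    return best


def nested_cv_predict(kernel_builder, y, confounds, scheme: CVScheme,
                      grid: HyperparamGrid | None = None, *, taus=None,
                      variable_name: str = "y") -> PredictionResult:
    """Nested-CV kernel ridge regression over a prebuilt fold scheme.

    ``kernel_builder(tau, train_idx)`` must return the full N x N kernel,
    using ``train_idx`` only for data-driven scales (never test targets);
    for linear kernels it is called once with tau=None.  Per outer fold the
    inner loop grid-searches (lambda, tau), the winner is refit on the full
    training fold and scored on the test fold.
    """
    grid = grid or HyperparamGrid()
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains missing values; remove those subjects first")
    confounds = None if confounds is None else np.asarray(confounds, dtype=float)
    y_range = float(y.max() - y.min())
    tau_grid = list(grid.taus) if taus is None else list(taus)
    if taus is None and getattr(kernel_builder, "linear", False):
        tau_grid = [None]

    rows = []
    for rep in range(scheme.n_repeats):
        for fold, (tr, te) in enumerate(scheme.outer[rep]):
            kernels = {tau: kernel_builder(tau, tr) for tau in tau_grid}
            lam, tau = _select_hyperparams(kernels, y, confounds,
                                           scheme.inner[rep][fold], grid.lambdas)
            Kfull = kernels[tau]
            if confounds is not None:
                y_tr, y_te, cmodel = deconfound(y[tr], y[te], confounds[tr], confounds[te])
                back = cmodel.predict(confounds[te])
            else:
                y_tr, y_te, back = y[tr], y[te], 0.0
            model = krr_fit(Kfull[np.ix_(tr, tr)], y_tr, lam, training_ids=tr)
            pred = krr_predict(model, Kfull[np.ix_(te, tr)])
            m = evaluate(y_te, pred, y[te], pred + back, y_range)
            rows.append({"variable": variable_name, "repeat": rep, "fold": fold,
                         "lambda": lam, "tau": np.nan if tau is None else tau, **m})
    return PredictionResult(pd.DataFrame(rows))


def linear_kernel_builder(features) -> callable:
    """Builder closure for a fixed linear kernel (tau is ignored)."""
    X = np.asarray(features, dtype=float)
    K = X @ X.T

    def build(tau, train_idx):
        return K

    build.linear = True
    return build


def gaussian_kernel_builder(features, relative: bool = True) -> callable:
    """Builder closure producing RBF kernels with train-scaled widths."""
    from .kernels import gaussian_kernel

    X = np.asarray(features, dtype=float)

    def build(tau, train_idx):
        return gaussian_kernel(X, tau, relative=relative, train_rows=train_idx)

    build.linear = False
    return build


def nested_cv_predict_features(features, y, confounds, scheme: CVScheme,
                               grid: HyperparamGrid | None = None, *,
                               variable_name: str = "y") -> PredictionResult:
    """Nested-CV primal ridge regression (with intercept) on raw features.

    The intercept is handled by centring features and target with
    training-fold means, which makes this the primal twin of kernel ridge
    with a linear kernel on centred features.
    """
    grid = grid or HyperparamGrid()
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    confounds = None if confounds is None else np.asarray(confounds, dtype=float)
    y_range = float(y.max() - y.min())

    def ridge_predict(Xtr, ytr, Xte, lam):
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        if Xc.shape[1] <= Xc.shape[0]:
            w = linalg.solve(Xc.T @ Xc + lam * np.eye(Xc.shape[1]), Xc.T @ yc,
                             assume_a="pos")
        else:  # dual route for wide feature matrices
            a = linalg.solve(Xc @ Xc.T + lam * np.eye(Xc.shape[0]), yc, assume_a="pos")
            w = Xc.T @ a
        return (Xte - xm) @ w + ym

    rows = []
    for rep in range(scheme.n_repeats):
        for fold, (tr, te) in enumerate(scheme.outer[rep]):
            best, best_score = None, -np.inf
            for lam in grid.lambdas:
                rs = []
                for itr, iva in scheme.inner[rep][fold]:
                    if confounds is not None:
                        y_tr, y_va, _ = deconfound(y[itr], y[iva], confounds[itr], confounds[iva])
                    else:
                        y_tr, y_va = y[itr], y[iva]
                    pred = ridge_predict(X[itr], y_tr, X[iva], lam)
                    r, _ = _pearson(pred, y_va)
                    rs.append(r)
                score = float(np.mean(rs))
                if score > best_score or (score == best_score and best is not None and lam > best):
                    best, best_score = lam, score
            if confounds is not None:
                y_tr, y_te, cmodel = deconfound(y[tr], y[te], confounds[tr], confounds[te])
                back = cmodel.predict(confounds[te])
            else:
                y_tr, y_te, back = y[tr], y[te], 0.0
            pred = ridge_predict(X[tr], y_tr, X[te], best)
            m = evaluate(y_te, pred, y[te], pred + back, y_range)
            rows.append({"variable": variable_name, "repeat": rep, "fold": fold,
                         "lambda": best, "tau": np.nan, **m})
    return PredictionResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def corrected_rkcv_ttest(acc_a, acc_b, k: int, r: int, n1: int, n2: int):
    """Repeated k-fold CV corrected t-test between two methods' accuracies.

    t = mean(x) / sqrt( (1/(k r) + n2/n1) * sigma^2 ) on the paired
    fold-by-repetition differences x, where n1/n2 are the training/test
    sizes; the variance correction accounts for the overlap between
    training sets across folds.  Two-sided p from t_{k r - 1}.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracy vectors must have equal length")
    x = a - b
    m = x.mean()
    var = x.var(ddof=1) if x.size > 1 else 0.0
    if var == 0:
        if m == 0:
            return 0.0, 1.0
        return float(np.sign(m) * np.inf), 0.0
    t = m / np.sqrt((1.0 / (k * r) + n2 / n1) * var)
    df = k * r - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
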