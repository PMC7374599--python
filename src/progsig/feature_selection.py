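"""Sparse signature discovery: LASSO with k-fold cross-validation, and
VIP-score thresholding.

The LASSO solves

    min_β  (1/2n) ‖y − Xβ‖² + λ ‖β‖₁

by cyclic coordinate descent with soft-thresholding, warm-started along a
geometric grid of 100 penalties from λ_max = max|Xᵀy|/n (where the solution
is exactly zero) down to 10⁻³ λ_max.  The penalty is chosen at the minimum
cross-validated mean squared prediction error; scaling parameters are always
fit on the training part of each fold and re-applied to the held-out part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._folds import balanced_stratified_folds
from .io import AnalyteTable

DEFAULT_TOL = 1e-7
DEFAULT_N_LAMBDAS = 100
DEFAULT_EPS = 1e-3


class EmptySignatureError(RuntimeError):
    """The selected penalty shrank every coefficient to zero."""


@dataclass
class Signature:
    """Ordered list of selected analytes with their selection weights."""

    analyte_ids: list[str]
    weights: np.ndarray
    method: str
    lambda_selected: float | None = None
    compartments: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.analyte_ids) != len(self.weights):
            raise ValueError("analyte_ids and weights differ in length")
        if len(self.analyte_ids) == 0:
            raise EmptySignatureError(f"empty signature from method {self.method!r}")
        if np.any(self.weights == 0):
            raise ValueError("signature weights must be nonzero")

    def __len__(self) -> int:
        return len(self.analyte_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"analyte_id": self.analyte_ids, "weight": self.weights})
        if self.compartments is not None:
            df["compartment"] = self.compartments
        df["method"] = self.method
        if self.lambda_selected is not None:
            df["lambda_selected"] = self.lambda_selected
        return df.set_index("analyte_id")


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------

try:  # JIT-compile the inner solver when numba is available
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=False)
def _cd_path_kernel(X, y, lambdas, beta_init, tol, max_iter):  # pragma: no cover - exercised via wrappers
    """Cyclic coordinate descent with soft-thresholding, residual updates,
    warm starts along a descending penalty grid, and an active-set strategy.
    Converges when the largest coefficient change in a sweep drops below tol.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    beta = beta_init.copy()
    r = y - X @ beta
    col_sq = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        col_sq[j] = s / n

    for li in range(n_lam):
        lam = lambdas[li]
        for _ in range(max_iter):
            # one full sweep
            worst = 0.0
            for j in range(p):
                g = col_sq[j]
                if g <= 0.0:
                    continue
                b_old = beta[j]
                dot = 0.0
                for i in range(n):
                    dot += X[i, j] * r[i]
                z = g * b_old + dot / n
                if z > lam:
                    b_new = (z - lam) / g
                elif z < -lam:
                    b_new = (z + lam) / g
                else:
                    b_new = 0.0
                d = b_new - b_old
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = b_new
                    if abs(d) > worst:
                        worst = abs(d)
            if worst < tol:
                break
            # iterate on the active set until it converges
            for _ in range(max_iter):
                worst_a = 0.0
                for j in range(p):
                    if beta[j] == 0.0:
                        continue
                    g = col_sq[j]
                    b_old = beta[j]
                    dot = 0.0
                    for i in range(n):
                        dot += X[i, j] * r[i]
                    z = g * b_old + dot / n
                    if z > lam:
                        b_new = (z - lam) / g
                    elif z < -lam:
                        b_new = (z + lam) / g
                    else:
                        b_new = 0.0
                    d = b_new - b_old
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= X[i, j] * d
                        beta[j] = b_new
                        if abs(d) > worst_a:
                            worst_a = abs(d)
                if worst_a < tol:
                    break
        betas[li] = beta
    return betas


def lasso_fit(X, y, lam: float, tol: float = DEFAULT_TOL, max_iter: int = 10_000, beta0=None) -> np.ndarray:
    """Solve the LASSO at a single penalty.

    ``X`` is expected autoscaled and ``y`` centred (the objective carries no
    intercept).  Returns the coefficient vector.
    """
    X = np.asfortranarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float).ravel()
    if lam < 0:
        raise ValueError(f"penalty must be nonnegative, got {lam}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in X or y")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    beta = np.zeros(X.shape[1]) if beta0 is None else np.ascontiguousarray(beta0, dtype=float)
    lambdas = np.asarray([float(lam)])
    return _cd_path_kernel(X, y, lambdas, beta, tol, max_iter)[0]


def lambda_grid(X, y, n_lambdas: int = DEFAULT_N_LAMBDAS, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Geometric penalty grid from λ_max (all-zero solution) down to eps·λ_max."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lam_max = np.abs(X.T @ y).max() / X.shape[0]
    if lam_max <= 0:
        raise ValueError("X'y is identically zero; no informative penalty grid exists")
    return np.geomspace(lam_max, eps * lam_max, n_lambdas)


def lasso_path(X, y, lambdas, tol: float = DEFAULT_TOL, max_iter: int = 10_000) -> np.ndarray:
    """Coefficients at each penalty of a descending grid, warm-started."""
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    X = np.asfortranarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in X or y")
    if np.any(lambdas < 0):
        raise ValueError("penalties must be nonnegative")
    beta0 = np.zeros(X.shape[1])
    return _cd_path_kernel(X, y, lambdas, beta0, tol, max_iter)


def _scale_train_test(train: np.ndarray, test: np.ndarray):
    """Centre/scale both sets with training-fold parameters; constant training
    columns are neutralised (zero after scaling) rather than dropped."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    tr = (train - mu) / sd_safe
    te = (test - mu) / sd_safe
    tr[:, ~ok] = 0.0
    te[:, ~ok] = 0.0
    return tr, te


class LassoSelector(TransformerMixin, BaseEstimator):
    """LASSO signature selection with seeded k-fold cross-validation.

    Parameters
    ----------
    cv : fold count (default 10); ``cv`` equal to n gives leave-one-out.
    n_lambdas, eps : penalty-grid size and extent (λ_max down to eps·λ_max).
    alpha : optional fixed penalty; skips cross-validation when given.
    random_state : seed for the fold assignment.

    Fitted attributes: ``coef_``, ``alpha_``, ``support_``, ``lambdas_``,
    ``mse_path_`` (per-λ CV mean squared error), ``fold_assignment_``.
    """

    def __init__(
        self,
        cv: int = 10,
        n_lambdas: int = DEFAULT_N_LAMBDAS,
        eps: float = DEFAULT_EPS,
        tol: float = DEFAULT_TOL,
        alpha: float | None = None,
        random_state: int = 0,
        null_guard: bool = True,
    ):
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.eps = eps
        self.tol = tol
        self.alpha = alpha
        self.random_state = random_state
        self.null_guard = null_guard

    def fit(self, X, y):
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if columns is None:
            columns = list(range(X.shape[1]))
        n = X.shape[0]
        if self.alpha is None and n < self.cv:
            raise ValueError(f"n={n} is smaller than cv={self.cv}")

        Xs, _ = _scale_train_test(X, X)
        yc = y - y.mean()
        grid = lambda_grid(Xs, yc, self.n_lambdas, self.eps)

        if self.alpha is None:
            folds = balanced_stratified_folds(y, self.cv, self.random_state)
            sq_err = np.zeros((len(grid), n))
            null_sq = np.zeros(n)  # intercept-only model
            for f in range(self.cv):
                te = folds == f
                tr = ~te
                Xtr, Xte = _scale_train_test(X[tr], X[te])
                ym = y[tr].mean()
                betas = lasso_path(Xtr, y[tr] - ym, grid, tol=self.tol)
                pred = ym + betas @ Xte.T  # (n_lambdas, n_test)
                sq_err[:, te] = (pred - y[te]) ** 2
                null_sq[te] = (ym - y[te]) ** 2
            mse = sq_err.mean(axis=1)
            best = int(np.argmin(mse))
            # null-model guard: the CV estimate of the MSE carries sampling
            # error; unless the minimum beats the intercept-only model by more
            # than one standard error of the per-fold means, prefer the empty
            # model and report no signature.
            if self.null_guard and best > 0:
                fold_means = np.asarray([sq_err[best, folds == f].mean() for f in range(self.cv)])
                se_best = fold_means.std(ddof=1) / np.sqrt(self.cv)
                if null_sq.mean() <= mse[best] + se_best:
                    best = 0
            self.mse_path_ = mse
            self.null_mse_ = float(null_sq.mean())
            self.fold_assignment_ = folds
            self.alpha_ = float(grid[best])
        else:
            self.mse_path_ = None
            self.fold_assignment_ = None
            self.alpha_ = float(self.alpha)

        warm = grid[grid >= self.alpha_]
        beta0 = lasso_path(Xs, yc, warm, tol=self.tol)[-1] if len(warm) else None
        beta = lasso_fit(Xs, yc, self.alpha_, tol=self.tol, beta0=beta0)
        # coefficients at the soft-threshold boundary can survive as pure
        # floating-point dust; they are zero for support purposes
        beta[np.abs(beta) <= 1e-9 * max(self.alpha_, np.abs(beta).max(initial=0.0))] = 0.0
        self.lambdas_ = grid
        self.coef_ = beta
        self.support_ = beta != 0
        self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def signature(self, compartments: dict[str, str] | None = None) -> Signature:
        """The selected analytes, ordered by |coefficient| descending."""
        check_is_fitted(self, "coef_")
        idx = np.flatnonzero(self.support_)
        if idx.size == 0:
            raise EmptySignatureError(
                f"LASSO selected no analytes at lambda={self.alpha_:.4g}; "
                "the response carries no detectable linear signal"
            )
        order = idx[np.argsort(-np.abs(self.coef_[idx]))]
        ids = [self.feature_names_in_[j] for j in order]
        comp = [compartments.get(a) for a in ids] if compartments else None
        return Signature(
            analyte_ids=ids,
            weights=self.coef_[order],
            method="lasso_cv" if self.alpha is None else "lasso",
            lambda_selected=self.alpha_,
            compartments=comp,
        )


def lasso_cv(
    X,
    y,
    k: int = 10,
    seed: int = 0,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    eps: float = DEFAULT_EPS,
    null_guard: bool = True,
) -> Signature:
    """LASSO signature with k-fold CV-selected penalty (minimum CV MSE).

    ``X`` may be an :class:`AnalyteTable` (raw concentrations; scaling is
    refit inside every fold) or a matrix; ``y`` is the numeric response
    (class coding 0/1 or ordinal time coding 0/1/2).
    """
    compartments = None
    if isinstance(X, AnalyteTable):
        compartments = dict(X.analyte_meta["compartment"])
        X = X.values
    sel = LassoSelector(cv=k, n_lambdas=n_lambdas, eps=eps, random_state=seed, null_guard=null_guard).fit(X, y)
    return sel.signature(compartments)


# ---------------------------------------------------------------------------
# VIP selection
# ---------------------------------------------------------------------------

def vip_select(model, cutoff: float = 1.0) -> Signature:
    """Analytes whose VIP score reaches ``cutoff``, ordered by VIP descending.

    ``model`` is a fitted :class:`progsig.plsda.PLSDAClassifier`.
    """
    vip = np.asarray(model.vip_)
    names = getattr(model, "feature_names_in_", np.arange(len(vip)).astype(object))
    keep = np.flatnonzero(vip >= cutoff)
    if keep.size == 0:
        raise EmptySignatureError(f"no analyte reaches VIP cutoff {cutoff}")
    order = keep[np.argsort(-vip[keep])]
    return Signature(
        analyte_ids=[names[j] for j in order],
        weights=vip[order],
        method="vip",
    )


class VIPSelector(TransformerMixin, BaseEstimator):
    """Select analytes by VIP score of an internally fitted PLSDA model."""

    def __init__(self, cutoff: float = 1.0, n_components: int = 2):
        self.cutoff = cutoff
        self.n_components = n_components

    def fit(self, X, y):
        from .plsda import PLSDAClassifier

        columns = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
        model = PLSDAClassifier(n_components=self.n_components).fit(X, y)
        self.model_ = model
        self.vip_ = model.vip_
        self.support_ = self.vip_ >= self.cutoff
        self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.n_features_in_ = len(columns)
        if not self.support_.any():
            raise EmptySignatureError(f"no analyte reaches VIP cutoff {self.cutoff}")
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def signature(self) -> Signature:
        check_is_fitted(self, "support_")
        return vip_select(self.model_, self.cutoff)
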