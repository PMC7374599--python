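"""Partial least squares discriminant analysis (PLS1/NIPALS) with
orthogonalisation, VIP scores, cross-validation and classification metrics.

The two classes are coded 0/1 (alphabetical order, so ``non_progressor`` → 0,
``progressor`` → 1) and a PLS1 regression is fit against the centred coding
by NIPALS with X-deflation per latent variable (LV).  A sample is assigned
the class whose code is nearest the continuous prediction (midpoint
threshold; exact ties go to the higher code).

Orthogonalisation post-rotates the fitted score space so LV1 carries all of
the class-predictive variation while the remaining LVs are uncorrelated with
the class coding; fitted values and predictions are unchanged.  LV1 is
oriented so the class coded 0 has a positive mean score.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._folds import balanced_stratified_folds
from .io import AnalyteTable

logger = logging.getLogger(__name__)

_TINY = 1e-12


class StratificationError(ValueError):
    """A class is absent from a training fold."""


def _as_matrix(X):
    if isinstance(X, AnalyteTable):
        X = X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, list(range(X.shape[1]))


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Two-class PLS discriminant analysis.

    Parameters
    ----------
    n_components : number of latent variables to extract.
    scale : autoscale X internally (mean centre + unit sample SD) with the
        training parameters re-applied at prediction time.  Pass ``False``
        when X is already autoscaled.
    orthogonalized : rotate the fitted model so LV1 is the predictive
        direction (see :func:`orthogonalize`).

    Fitted attributes follow the chemometrics naming: ``x_weights_`` (W,
    unit-norm columns), ``x_scores_`` (T, mutually orthogonal columns),
    ``x_loadings_`` (P), ``y_loadings_`` (q), ``vip_``,
    ``explained_x_variance_`` (per-LV fraction of the autoscaled X variance),
    ``coef_`` (regression vector), ``classes_`` and ``class_codes_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = True, orthogonalized: bool = False):
        self.n_components = n_components
        self.scale = scale
        self.orthogonalized = orthogonalized

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, columns = _as_matrix(X)
        y = np.asarray(y)
        n, p = X.shape
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"PLSDA requires exactly two classes, got {list(classes)}")
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )
        self.classes_ = classes
        self.class_codes_ = {classes[0]: 0.0, classes[1]: 1.0}
        y_num = np.where(y == classes[1], 1.0, 0.0)

        if self.scale:
            self.x_means_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            ok = sd > 0
            self.x_sds_ = np.where(ok, sd, 1.0)
            self._live_cols_ = ok
            Xs = (X - self.x_means_) / self.x_sds_
            Xs[:, ~ok] = 0.0
        else:
            self.x_means_ = np.zeros(p)
            self.x_sds_ = np.ones(p)
            self._live_cols_ = np.ones(p, dtype=bool)
            Xs = X.copy()

        self.y_mean_ = float(y_num.mean())
        A = self.n_components
        Xd = Xs.copy()
        yd = y_num - self.y_mean_
        ss_x = float(np.sum(Xs * Xs))
        if ss_x <= _TINY:
            raise ValueError("X has no variance after scaling")
        self._ss_x_ = ss_x

        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ssy = np.zeros(A)
        expl = np.zeros(A)
        for a in range(A):
            w = Xd.T @ yd
            nw = float(np.linalg.norm(w))
            if nw <= _TINY:
                raise ValueError(
                    f"n_components={A} exceeds the predictive rank of X (stopped at LV {a})"
                )
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            if tt <= _TINY:
                raise ValueError(f"n_components={A} exceeds the rank of X (stopped at LV {a})")
            pa = Xd.T @ t / tt
            qa = float(yd @ t / tt)
            Xd -= np.outer(t, pa)
            yd = yd - t * qa
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
            ssy[a] = qa**2 * tt
            expl[a] = tt * float(pa @ pa) / ss_x

        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.ssy_ = ssy
        self.explained_x_variance_ = expl
        self._score_proj_ = W @ np.linalg.inv(P.T @ W)
        self.coef_ = self._score_proj_ @ q
        self.vip_ = vip_scores(self)
        self.orthogonalized_ = False
        self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.n_features_in_ = p
        self._y_train_codes_ = y_num
        if self.orthogonalized:
            _orthogonalize_inplace(self)
        return self

    # ------------------------------------------------------------- predict
    def _check_X(self, X):
        X, columns = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} analytes, got {X.shape[1]}")
        if list(columns) != list(self.feature_names_in_) and not all(
            isinstance(c, int) for c in columns
        ):
            raise ValueError("analyte mismatch: columns differ from the fitted model")
        Xs = (X - self.x_means_) / self.x_sds_
        Xs[:, ~self._live_cols_] = 0.0
        return Xs

    def decision_function(self, X) -> np.ndarray:
        """Continuous PLS prediction of the class code."""
        check_is_fitted(self, "coef_")
        return self.y_mean_ + self._check_X(X) @ self.coef_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        midpoint = 0.5  # codes are 0 and 1; exact ties go to the higher code
        return np.where(score >= midpoint, self.classes_[1], self.classes_[0])

    def transform(self, X) -> np.ndarray:
        """Latent-variable scores for new samples."""
        check_is_fitted(self, "coef_")
        return self._check_X(X) @ self._score_proj_


# ---------------------------------------------------------------------------
# orthogonalisation
# ---------------------------------------------------------------------------

def _orthogonalize_inplace(model: PLSDAClassifier) -> None:
    A = model.x_scores_.shape[1]
    if A < 2:
        logger.warning("orthogonalisation of a 1-LV model is the identity")
        model.orthogonalized_ = True
        return
    T, P, q = model.x_scores_, model.x_loadings_, model.y_loadings_
    t_pred = T @ q
    if np.linalg.norm(t_pred) <= _TINY:
        logger.warning("predictive score direction is null; skipping orthogonalisation")
        return
    Qfull, _ = np.linalg.qr(np.column_stack([t_pred, T]))
    Qb = Qfull[:, :A]  # orthonormal basis with first direction = prediction
    C = T.T @ Qb / (T * T).sum(axis=0)[:, None]  # original-score coords of Qb
    p_new = P @ (T.T @ Qb)  # = X^T Qb (residual E is orthogonal to span(T))
    norms = np.linalg.norm(p_new, axis=0)
    norms[norms <= _TINY] = 1.0
    T_new = Qb * norms
    P_new = p_new / norms
    yc = model._y_train_codes_ - model.y_mean_
    q_new = T_new.T @ yc / (T_new * T_new).sum(axis=0)
    W_new = model.x_weights_ @ C
    wn = np.linalg.norm(W_new, axis=0)
    wn[wn <= _TINY] = 1.0
    W_new = W_new / wn
    rotation = C * norms[None, :]

    # orient LV1 so the class coded 0 has positive mean score
    neg_class_rows = model._y_train_codes_ == 0.0
    if T_new[neg_class_rows, 0].mean() < 0:
        T_new[:, 0] *= -1
        P_new[:, 0] *= -1
        W_new[:, 0] *= -1
        q_new[0] *= -1
        rotation[:, 0] *= -1

    model.explained_x_variance_ = norms**2 / model._ss_x_
    model.x_scores_ = T_new
    model.x_loadings_ = P_new
    model.x_weights_ = W_new
    model.y_loadings_ = q_new
    model._score_proj_ = model._score_proj_ @ rotation
    model.orthogonalized_ = True


def orthogonalize(model: PLSDAClassifier) -> PLSDAClassifier:
    """Return a copy of the model rotated so LV1 carries the class-predictive
    variation; predictions and fitted values are unchanged."""
    check_is_fitted(model, "coef_")
    out = _copy.deepcopy(model)
    if not out.orthogonalized_:
        _orthogonalize_inplace(out)
    return out


def vip_scores(model: PLSDAClassifier) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ), where SSY_a is
    the y-variance explained by LV a.  Mean squared VIP over analytes is 1.
    """
    check_is_fitted(model, "x_weights_")
    W = model.x_weights_
    ssy = np.asarray(model.ssy_, dtype=float)
    if ssy.sum() <= 0:
        raise ValueError("degenerate model: no explained y-variance")
    wn = np.linalg.norm(W, axis=0)
    wn[wn <= _TINY] = 1.0
    w2 = (W / wn) ** 2
    p = W.shape[0]
    return np.sqrt(p * (w2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# functional wrappers and model evaluation
# ---------------------------------------------------------------------------

def fit_plsda(X, classes, n_lv: int = 2, orthogonalized: bool = False) -> PLSDAClassifier:
    """Fit PLSDA on an autoscaled matrix (no internal re-scaling)."""
    return PLSDAClassifier(n_components=n_lv, scale=False, orthogonalized=orthogonalized).fit(X, classes)


def predict(model: PLSDAClassifier, X_new) -> tuple[np.ndarray, np.ndarray]:
    """(class, continuous score) for new samples scaled like the model."""
    return model.predict(X_new), model.decision_function(X_new)


@dataclass
class ClassificationMetrics:
    """Confusion counts and derived proportions for a binary classifier."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: list[str] = field(default_factory=list)


def classification_metrics(predicted, truth, positive_class) -> ClassificationMetrics:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth differ in length")
    pos_t = truth == positive_class
    pos_p = predicted == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ClassificationMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(truth),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=undefined,
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scores, truth, positive_class=None) -> ROCCurve:
    """Threshold sweep over the continuous scores with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if len(classes) != 2:
        raise ValueError(f"ROC needs both classes present, got {list(classes)}")
    if positive_class is None:
        positive_class = classes[1]
    y = (truth == positive_class).astype(int)
    fpr, tpr, thr = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_skmetrics.auc(fpr, tpr)))


@dataclass
class CVResult:
    """Seeded stratified k-fold cross-validation of a PLSDA model."""

    per_fold_accuracy: list[float]
    pooled_cv_accuracy: float
    per_sample_prediction: np.ndarray
    per_sample_score: np.ndarray
    fold_assignment: np.ndarray
    n_lv_per_fold: list[int]


def _choose_n_lv(X, y, n_lv_max: int, seed: int, inner_k: int = 5) -> int:
    """Inner-CV choice of the LV count: minimise held-out squared error of
    the continuous prediction."""
    n = len(y)
    classes, y_num = np.unique(y, return_inverse=True)
    k = min(inner_k, n)
    folds = balanced_stratified_folds(y, k, seed)
    cap = min(n_lv_max, n - int(np.bincount(folds).max()) - 1, X.shape[1])
    cap = max(cap, 1)
    sq = np.zeros((cap, n))
    ok = np.ones(cap, dtype=bool)
    for f in range(k):
        te = folds == f
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            raise StratificationError("a class is absent from an inner training fold")
        for a in range(1, cap + 1):
            if not ok[a - 1]:
                continue
            try:
                m = PLSDAClassifier(n_components=a, scale=True).fit(X[tr], y[tr])
            except ValueError:
                ok[a - 1] = False
                continue
            sq[a - 1, te] = (m.decision_function(X[te]) - y_num[te]) ** 2
    err = np.where(ok, sq.mean(axis=1), np.inf)
    return int(np.argmin(err) + 1)


def cross_validate(X, classes, k: int = 10, seed: int = 0, n_lv_max: int = 10) -> CVResult:
    """Stratified k-fold CV with scaling and LV-count choice refit per fold.

    ``X`` holds raw (unscaled) values; each training fold is autoscaled, its
    LV count picked by an inner 5-fold error minimum, and the held-out fold
    evaluated with the training fold's scaling.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(classes)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    folds = balanced_stratified_folds(y, k, seed)
    pred = np.empty(n, dtype=y.dtype)
    score = np.empty(n, dtype=float)
    per_fold, n_lvs = [], []
    for f in range(k):
        te = folds == f
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            raise StratificationError(f"a class is absent from training fold {f}")
        a = _choose_n_lv(X[tr], y[tr], n_lv_max, seed + 1000 + f)
        model = PLSDAClassifier(n_components=a, scale=True).fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
        score[te] = model.decision_function(X[te])
        per_fold.append(float(np.mean(pred[te] == y[te])))
        n_lvs.append(a)
    return CVResult(
        per_fold_accuracy=per_fold,
        pooled_cv_accuracy=float(np.mean(pred == y)),
        per_sample_prediction=pred,
        per_sample_score=score,
        fold_assignment=folds,
        n_lv_per_fold=n_lvs,
    )
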