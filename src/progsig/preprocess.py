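"""Autoscaling and iterative Hotelling reduced-T² sample pruning.

Autoscaling (mean centring + unit-variance scaling with the n−1 denominator)
is fit on calibration data and re-applied to held-out data so that
cross-validation never leaks test-fold information.

"Negative drivers" are samples that dominate a PCA model of the autoscaled
data.  Each sample's Hotelling T² in the retained score space is divided by
the F-based 95% confidence limit

    T²₉₅ = A(n−1)(n+1) / (n(n−A)) · F₀.₉₅(A, n−A)

to give a *reduced* T²; the sample with the largest reduced T² above 5 is
removed and the PCA refit, iterating until all samples score below 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import AnalyteTable

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Raised when autoscaling meets constant analytes and may not drop them."""

    def __init__(self, analytes):
        self.analytes = list(analytes)
        super().__init__(f"zero-variance analyte(s): {self.analytes[:10]}")


@dataclass
class ScalingParams:
    """Per-analyte centring/scaling parameters (sample SD, ddof=1)."""

    means: pd.Series
    sds: pd.Series

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values[self.means.index] - self.means) / self.sds


class Autoscaler(TransformerMixin, BaseEstimator):
    """Mean-centring and unit-variance scaling with the n−1 denominator.

    Unlike ``StandardScaler`` this uses the sample (ddof=1) standard
    deviation, the convention of chemometrics toolboxes.  Zero-variance
    columns either raise (``on_constant='raise'``) or are dropped with a
    warning (``on_constant='drop'``).
    """

    def __init__(self, on_constant: str = "raise"):
        self.on_constant = on_constant

    def fit(self, X, y=None):
        if self.on_constant not in ("raise", "drop"):
            raise ValueError(f"on_constant must be 'raise' or 'drop', got {self.on_constant!r}")
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, ensure_min_samples=2)
        if columns is None:
            columns = list(range(X.shape[1]))
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        constant = np.asarray(sds) <= 0
        if constant.any():
            bad = [columns[i] for i in np.flatnonzero(constant)]
            if self.on_constant == "raise":
                raise ZeroVarianceError(bad)
            logger.warning("dropping %d zero-variance analyte(s): %s", len(bad), bad[:10])
        keep = ~constant
        self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.support_ = keep
        self.means_ = means[keep]
        self.sds_ = sds[keep]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        if isinstance(X, pd.DataFrame):
            cols = [c for c, k in zip(self.feature_names_in_, self.support_) if k]
            return (X[cols] - self.means_) / self.sds_
        X = check_array(X)
        return (X[:, self.support_] - self.means_) / self.sds_

    def get_params_series(self) -> ScalingParams:
        check_is_fitted(self, "means_")
        kept = [c for c, k in zip(self.feature_names_in_, self.support_) if k]
        return ScalingParams(
            means=pd.Series(self.means_, index=kept),
            sds=pd.Series(self.sds_, index=kept),
        )


def autoscale(table: AnalyteTable, on_constant: str = "raise") -> tuple[AnalyteTable, ScalingParams]:
    """Autoscale an analyte table; returns the scaled table plus the fitted
    parameters for re-applying the identical transform to held-out samples."""
    if table.values.isna().any().any():
        na = table.values.columns[table.values.isna().any()][:5]
        raise ValueError(f"autoscale requires imputed data; NaN in analyte(s) {list(na)}")
    scaler = Autoscaler(on_constant=on_constant).fit(table.values)
    scaled = scaler.transform(table.values)
    out = table.subset_analytes(list(scaled.columns))
    out.values = scaled
    return out, scaler.get_params_series()


# ---------------------------------------------------------------------------
# Hotelling reduced T²
# ---------------------------------------------------------------------------

def _reduced_t2_scores(X: np.ndarray, var_fraction: float) -> tuple[np.ndarray, int]:
    """Reduced-T² per sample of an autoscaled (or at least centred) matrix.

    Returns (scores, A) with A the retained PCA component count: the smallest
    number of components whose cumulative explained variance reaches
    ``var_fraction``, capped at n−2 so the F limit stays defined.
    """
    n, p = X.shape
    if not 0.0 < var_fraction <= 1.0:
        raise ValueError(f"var_fraction must be in (0, 1], got {var_fraction}")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)  # PCA eigenvalues
    pos = lam > max(lam.max(), 1.0) * 1e-12
    lam, u, s = lam[pos], u[:, pos], s[pos]
    cum = np.cumsum(lam) / lam.sum()
    A = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
    A = min(A, n - 2, len(lam))
    if A < 1:
        raise ValueError("insufficient samples for reduced T2 (need n >= 3)")
    scores = u[:, :A] * s[:A]  # PCA scores t_ia
    t2 = np.sum(scores**2 / lam[:A], axis=1)
    f95 = stats.f.ppf(0.95, A, n - A)
    t2_95 = A * (n - 1) * (n + 1) / (n * (n - A)) * f95
    return t2 / t2_95, A


def reduced_t2(table: AnalyteTable | pd.DataFrame | np.ndarray, var_fraction: float = 0.9) -> pd.Series:
    """Per-sample Hotelling reduced-T² score (T² over its 95% limit).

    Expects autoscaled data; values > 1 lie outside the 95% confidence
    ellipsoid of the retained PCA score space.
    """
    if isinstance(table, AnalyteTable):
        values = table.values
    elif isinstance(table, pd.DataFrame):
        values = table
    else:
        values = pd.DataFrame(np.asarray(table, dtype=float))
    scores, _ = _reduced_t2_scores(values.to_numpy(dtype=float), var_fraction)
    return pd.Series(scores, index=values.index, name="reduced_t2")


@dataclass
class OutlierReport:
    """Record of the iterative negative-driver removal loop."""

    removed_sample_ids: list[str] = field(default_factory=list)
    t2_trace: list[float] = field(default_factory=list)
    n_components_used: list[int] = field(default_factory=list)


class ReducedT2Pruner(BaseEstimator):
    """Iterative removal of PCA negative-driver samples.

    Each iteration autoscales the remaining samples, fits a PCA retaining
    ``var_fraction`` cumulative variance, and removes the single sample whose
    reduced T² is largest if it exceeds ``threshold``; the loop stops when
    every sample scores below the threshold.

    Attributes (after ``fit``): ``support_`` boolean keep-mask,
    ``removed_idx_``, ``report_``.
    """

    def __init__(self, threshold: float = 5.0, var_fraction: float = 0.9, max_removed_frac: float = 0.5):
        self.threshold = threshold
        self.var_fraction = var_fraction
        self.max_removed_frac = max_removed_frac

    def fit(self, X, y=None):
        values = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        n0 = len(values)
        if n0 < 10:
            raise ValueError(f"need at least 10 samples to prune negative drivers, got {n0}")
        report = OutlierReport()
        keep = values.index.to_list()
        while True:
            sub = values.loc[keep]
            scaler = Autoscaler(on_constant="drop").fit(sub)
            scaled = scaler.transform(sub)
            scores, A = _reduced_t2_scores(scaled.to_numpy(dtype=float), self.var_fraction)
            worst = int(np.argmax(scores))
            if scores[worst] <= self.threshold:
                break
            report.removed_sample_ids.append(keep[worst])
            report.t2_trace.append(float(scores[worst]))
            report.n_components_used.append(A)
            del keep[worst]
            if n0 - len(keep) > self.max_removed_frac * n0:
                raise RuntimeError(
                    f"reduced-T2 pruning would remove more than {self.max_removed_frac:.0%} of samples "
                    f"({n0 - len(keep)}/{n0}); data look globally inconsistent"
                )
        for sid, t2 in zip(report.removed_sample_ids, report.t2_trace):
            logger.info("removed negative driver %s (reduced T2 = %.2f)", sid, t2)
        self.support_ = values.index.isin(keep)
        self.removed_idx_ = list(report.removed_sample_ids)
        self.report_ = report
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[~X.index.isin(self.removed_idx_)]
        return np.asarray(X)[self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def prune_negative_drivers(
    table: AnalyteTable, threshold: float = 5.0, var_fraction: float = 0.9, max_removed_frac: float = 0.5
) -> tuple[AnalyteTable, OutlierReport]:
    """Run the iterative reduced-T² loop on a (raw-scale) analyte table.

    Autoscaling is refit at every iteration, matching refitting the PCA on
    the remaining data.  Returns the pruned table and the removal report.
    """
    pruner = ReducedT2Pruner(threshold=threshold, var_fraction=var_fraction, max_removed_frac=max_removed_frac)
    pruner.fit(table.values)
    kept = [s for s in table.sample_ids if s not in set(pruner.removed_idx_)]
    return table.subset_samples(kept), pruner.report_
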