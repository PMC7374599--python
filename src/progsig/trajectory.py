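"""Temporal analysis of longitudinal blood proteomics.

Within one clinical group, the three collection time points (weeks 0/48/80,
coded ordinally 0/1/2) are treated as the response of a cross-validated
LASSO; the selected temporal signature feeds a PCA over the pooled
(autoscaled) observations, and the separation of time points is judged by a
one-way ANOVA with Tukey's HSD post hoc test on the PC1 scores, plus kernel
density summaries of the per-time-point PC1 distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .feature_selection import Signature, lasso_cv
from .io import AnalyteTable
from .model_comparison import AnovaResult

TIME_CODES = {0: 0.0, 48: 1.0, 80: 2.0}


def _pooled_group_values(tables: dict[int, AnalyteTable], group: str) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Stack one group's samples across time points; returns (values, time
    codes, subject ids)."""
    weeks = sorted(tables)
    if len(weeks) < 2:
        raise ValueError("need at least 2 distinct time points")
    frames, codes, subjects = [], [], []
    for w in weeks:
        t = tables[w]
        keep = t.sample_meta["group"] == group
        if not keep.any():
            raise KeyError(f"no samples with group {group!r} at week {w}")
        frames.append(t.values.loc[keep.values])
        codes.extend([TIME_CODES.get(w, float(w))] * int(keep.sum()))
        subjects.extend(t.sample_meta.loc[keep.values, "subject_id"])
    values = pd.concat(frames, axis=0)
    return values, np.asarray(codes, dtype=float), subjects


def temporal_signature(
    tables: dict[int, AnalyteTable], group: str, k: int = 10, seed: int = 0
) -> Signature:
    """LASSO signature separating the collection time points within a group.

    Observations from all time points are pooled with the ordinal time code
    as the regression response.  Raises
    :class:`progsig.feature_selection.EmptySignatureError` when the selected
    penalty keeps no analyte (no detectable temporal signal).
    """
    values, codes, _ = _pooled_group_values(tables, group)
    compartments = dict(tables[sorted(tables)[0]].analyte_meta["compartment"])
    sig = lasso_cv(values, codes, k=k, seed=seed)
    sig.method = "lasso_cv_temporal"
    sig.compartments = [compartments.get(a) for a in sig.analyte_ids]
    return sig


@dataclass
class KernelDensity:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


def gaussian_kde(scores, grid=None, n_grid: int = 512) -> KernelDensity:
    """Gaussian-kernel density with the normal-reference bandwidth
    h = σ̂ (4 / 3n)^{1/5} (the classic default for a normal smoothing kernel)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 scores for a density")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return KernelDensity(grid=np.asarray([x[0]]), density=np.asarray([np.inf]), bandwidth=0.0, degenerate=True)
    h = sd * (4.0 / (3.0 * x.size)) ** 0.2
    if grid is None:
        grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
    grid = np.asarray(grid, dtype=float)
    u = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * u**2).sum(axis=1) / (x.size * h * math.sqrt(2 * math.pi))
    return KernelDensity(grid=grid, density=dens, bandwidth=h)


@dataclass
class TrajectoryModel:
    """PCA of a temporal signature with per-time-point score summaries."""

    signature: Signature
    scores: pd.DataFrame           # columns PC1, PC2, ... plus time_week, subject_id
    explained_variance: np.ndarray  # per-PC fraction
    per_time_pc1: dict[int, np.ndarray]
    group: str

    def pc12_variance(self) -> float:
        return float(self.explained_variance[: min(2, len(self.explained_variance))].sum())


def trajectory_pca(
    tables: dict[int, AnalyteTable], signature: Signature | list, group: str, n_components: int = 2
) -> TrajectoryModel:
    """PCA over the pooled, autoscaled signature expression of one group,
    with observations labelled by collection time point."""
    ids = list(signature.analyte_ids) if isinstance(signature, Signature) else list(signature)
    if not ids:
        raise ValueError("empty signature")
    for w, t in tables.items():
        missing = [a for a in ids if a not in t.values.columns]
        if missing:
            raise KeyError(f"signature analyte(s) missing at week {w}: {missing[:5]}")
    values, codes, subjects = _pooled_group_values(tables, group)
    X = values[ids].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant signature analyte(s) in group {group!r}: {bad[:5]}")
    Xs = (X - mu) / sd

    n_pc = int(min(n_components, Xs.shape[0] - 1, Xs.shape[1]))
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(Xs)

    # map the ordinal codes back to weeks for labelling
    code_to_week = {v: k for k, v in TIME_CODES.items()}
    weeks = np.asarray([int(code_to_week.get(c, c)) for c in codes])
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(n_pc)], index=values.index)
    df["time_week"] = weeks
    df["subject_id"] = subjects
    per_time = {int(w): df.loc[df["time_week"] == w, "PC1"].to_numpy() for w in np.unique(weeks)}
    sig = signature if isinstance(signature, Signature) else Signature(ids, np.ones(len(ids)), method="fixed")
    return TrajectoryModel(
        signature=sig,
        scores=df,
        explained_variance=pca.explained_variance_ratio_,
        per_time_pc1=per_time,
        group=group,
    )


class TrajectoryPCA:
    """Estimator-style wrapper: fit a trajectory PCA for one group."""

    def __init__(self, signature, group: str, n_components: int = 2):
        self.signature = signature
        self.group = group
        self.n_components = n_components

    def fit(self, tables: dict[int, AnalyteTable]):
        self.model_ = trajectory_pca(tables, self.signature, self.group, self.n_components)
        self.explained_variance_ratio_ = self.model_.explained_variance
        return self

    def get_params(self, deep: bool = True):
        return {"signature": self.signature, "group": self.group, "n_components": self.n_components}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def pc1_anova(model: TrajectoryModel) -> AnovaResult:
    """One-way ANOVA + Tukey HSD over the per-time-point PC1 scores.

    Time points with fewer than 2 observations are excluded (with a warning
    in the returned table's absence).
    """
    groups = {f"week{w}": v for w, v in sorted(model.per_time_pc1.items()) if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 time points with >= 2 observations")
    arrays = list(groups.values())
    if all(a.var(ddof=1) == 0 for a in arrays) and np.ptp([a.mean() for a in arrays]) == 0:
        names = list(groups.keys())
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
        tukey = pd.DataFrame(
            {"model_a": [a for a, _ in pairs], "model_b": [b for _, b in pairs],
             "mean_diff": 0.0, "p_adjusted": float("nan")}
        )
        return AnovaResult(f=float("nan"), p_value=float("nan"), tukey=tukey, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    names = list(groups.keys())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "model_a": names[i],
                    "model_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adjusted": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaResult(f=float(f), p_value=float(p), tukey=pd.DataFrame(rows))


def kde_pc1(model: TrajectoryModel, n_grid: int = 512) -> dict[int, KernelDensity]:
    """Per-time-point Gaussian kernel density of the PC1 scores, evaluated on
    a shared grid spanning all scores ± 4 bandwidths."""
    per_time = {w: v for w, v in model.per_time_pc1.items() if len(v) >= 2}
    if not per_time:
        raise ValueError("no time point has >= 2 scores")
    all_scores = np.concatenate(list(per_time.values()))
    h_max = 0.0
    for v in per_time.values():
        sd = v.std(ddof=1)
        if sd > 0:
            h_max = max(h_max, sd * (4.0 / (3.0 * v.size)) ** 0.2)
    pad = 4 * h_max if h_max > 0 else 1.0
    grid = np.linspace(all_scores.min() - pad, all_scores.max() + pad, n_grid)
    return {w: gaussian_kde(v, grid=grid) for w, v in sorted(per_time.items())}
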