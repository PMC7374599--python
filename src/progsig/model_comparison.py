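"""Statistical comparison of classifiers.

Calibration accuracies are compared on matched per-patient classification
states (correct/incorrect per model) with Cochran's Q and pairwise McNemar
post hoc tests (Bonferroni-adjusted).  Cross-validation accuracies are
compared treating the k per-fold accuracies of each model as replicates in a
one-way ANOVA with Tukey's HSD post hoc test.

Pairwise McNemar uses the exact two-tailed binomial test when the discordant
count b + c is below 25 and the continuity-corrected chi-squared statistic
(|b − c| − 1)² / (b + c) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

EXACT_MCNEMAR_MAX = 25  # switch to asymptotic chi-squared at b+c >= this


def _as_class_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    """Coerce a patients × models correct/incorrect matrix to 0/1."""
    if isinstance(matrix, pd.DataFrame):
        names = [str(c) for c in matrix.columns]
        x = matrix.to_numpy()
    else:
        x = np.asarray(matrix)
        names = [f"model_{j}" for j in range(x.shape[1])]
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two model columns")
    x = x.astype(float)
    if np.isnan(x).any():
        raise ValueError("classification matrix has missing cells")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("cells must be dichotomous (0/1 or bool)")
    return x.astype(int), names


@dataclass
class CochranQResult:
    q: float
    p_value: float
    df: int
    no_discordance: bool = False


def cochran_q(matrix) -> CochranQResult:
    """Cochran's Q over k ≥ 2 matched dichotomous outcomes.

    Rows where every model agrees (all correct or all incorrect) contribute
    nothing to the statistic.  If *no* row is discordant the statistic is
    undefined and the result carries a ``no_discordance`` flag.
    """
    x, _ = _as_class_matrix(matrix)
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    row_tot = x.sum(axis=1)
    if np.all((row_tot == 0) | (row_tot == k)):
        # every row concordant: the statistic's denominator vanishes.  The
        # models are indistinguishable, so report Q = 0, p = 1 and flag it.
        return CochranQResult(q=0.0, p_value=1.0, df=k - 1, no_discordance=True)
    res = _sm_cochrans_q(x, return_object=True)
    return CochranQResult(q=float(res.statistic), p_value=float(res.pvalue), df=k - 1)


@dataclass
class PairwiseMcNemar:
    model_a: str
    model_b: str
    b: int  # A correct, B wrong
    c: int  # B correct, A wrong
    statistic: float | None
    p_value: float
    p_adjusted: float
    exact: bool
    no_discordance: bool = False


def mcnemar_pair(correct_a, correct_b) -> tuple[int, int, float | None, float, bool]:
    """Discordant counts and McNemar p for one model pair."""
    a = np.asarray(correct_a).astype(int)
    bvec = np.asarray(correct_b).astype(int)
    b = int(np.sum((a == 1) & (bvec == 0)))
    c = int(np.sum((a == 0) & (bvec == 1)))
    if b + c == 0:
        return b, c, None, 1.0, True
    table = [[0, b], [c, 0]]  # only the discordant cells matter
    exact = (b + c) < EXACT_MCNEMAR_MAX
    res = _sm_mcnemar(table, exact=exact, correction=True)
    stat = None if exact else float(res.statistic)
    return b, c, stat, float(min(res.pvalue, 1.0)), exact


def mcnemar_posthoc(matrix, adjust: str = "bonferroni") -> list[PairwiseMcNemar]:
    """All pairwise McNemar tests with Bonferroni adjustment across pairs."""
    if adjust != "bonferroni":
        raise ValueError(f"only Bonferroni adjustment is supported, got {adjust!r}")
    x, names = _as_class_matrix(matrix)
    k = x.shape[1]
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            b, c, stat, p, exact = mcnemar_pair(x[:, i], x[:, j])
            out.append(
                PairwiseMcNemar(
                    model_a=names[i],
                    model_b=names[j],
                    b=b,
                    c=c,
                    statistic=stat,
                    p_value=p,
                    p_adjusted=min(1.0, p * n_pairs),
                    exact=exact if b + c else True,
                    no_discordance=(b + c == 0),
                )
            )
    return out


@dataclass
class AnovaResult:
    f: float
    p_value: float
    tukey: pd.DataFrame  # per-pair mean difference and adjusted p
    degenerate: bool = False


def fold_accuracy_anova(accuracies: dict | list, model_names=None) -> AnovaResult:
    """One-way ANOVA over per-fold CV accuracies with Tukey HSD post hoc.

    ``accuracies`` maps model name → list of k fold accuracies (or is a list
    of such lists).  Folds are treated as independent replicates.
    """
    if isinstance(accuracies, dict):
        names = list(accuracies.keys())
        groups = [np.asarray(v, dtype=float) for v in accuracies.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in accuracies]
        names = list(model_names) if model_names is not None else [f"model_{j}" for j in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("need at least two models to compare")
    sizes = {len(g) for g in groups}
    if len(sizes) != 1 or min(sizes) < 2:
        raise ValueError("every model needs the same number (>= 2) of fold accuracies")

    within_var = sum(float(g.var(ddof=1)) for g in groups)
    means = [g.mean() for g in groups]
    if within_var == 0.0 and np.ptp(means) == 0.0:
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
        tukey = pd.DataFrame(
            {"model_a": [a for a, _ in pairs], "model_b": [b for _, b in pairs],
             "mean_diff": 0.0, "p_adjusted": float("nan")}
        )
        return AnovaResult(f=float("nan"), p_value=float("nan"), tukey=tukey, degenerate=True)

    f, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "model_a": names[i],
                    "model_b": names[j],
                    "mean_diff": float(means[i] - means[j]),
                    "p_adjusted": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaResult(f=float(f), p_value=float(p), tukey=pd.DataFrame(rows))
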