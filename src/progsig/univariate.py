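"""Per-analyte volcano statistics and Pearson correlation.

Fold changes and t-tests run on raw (unscaled) concentrations: the fold
change is the ratio of group means (progressor over non-progressor), the
test is the pooled-variance two-sample Student t, and multiplicity is
handled with the Bonferroni correction only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalyteTable
from .synthetic import NON_PROGRESSOR, PROGRESSOR


def fold_change(x_prog, y_nonprog) -> float:
    """Ratio of group means; > 1 means elevated in the first (progressor) group."""
    x = np.asarray(x_prog, dtype=float)
    y = np.asarray(y_nonprog, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    my = y.mean()
    if my == 0:
        raise ZeroDivisionError("non-progressor mean is zero; fold change undefined")
    return float(x.mean() / my)


def two_sample_ttest(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test; pooled-variance Student t by default.

    ``welch=True`` switches to the unequal-variance form.  Zero pooled
    variance with equal means returns (0, 1) by convention; with unequal
    means it is an error (the statistic would be infinite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t statistic undefined")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean flags: True iff p < alpha / m with m the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.size


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def volcano(
    table: AnalyteTable,
    group_col: str = "group",
    positive_group: str = PROGRESSOR,
    negative_group: str = NON_PROGRESSOR,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Volcano-plot table: per-analyte fold change, t-test p, and
    significance flags at 0.05 / 0.01 / Bonferroni-corrected 0.05."""
    groups = table.sample_meta[group_col]
    xp = table.values.loc[(groups == positive_group).values].to_numpy(dtype=float)
    xn = table.values.loc[(groups == negative_group).values].to_numpy(dtype=float)
    if xp.shape[0] < 2 or xn.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples for the volcano analysis")
    mean_n = xn.mean(axis=0)
    if np.any(mean_n == 0):
        raise ZeroDivisionError("zero non-progressor mean: fold change undefined for some analyte")
    fc = xp.mean(axis=0) / mean_n
    t, p = stats.ttest_ind(xp, xn, axis=0, equal_var=not welch)
    # constant-in-both-groups analytes: p undefined -> equal means give p=1
    flat = np.isnan(p)
    if flat.any():
        equal = np.isclose(xp.mean(axis=0)[flat], xn.mean(axis=0)[flat])
        if not equal.all():
            raise ValueError("zero pooled variance with unequal means in volcano t-test")
        t = np.where(np.isnan(t), 0.0, t)
        p = np.where(np.isnan(p), 1.0, p)
    bonf = bonferroni(p, alpha=alpha)
    return pd.DataFrame(
        {
            "analyte_id": table.analyte_ids,
            "compartment": table.analyte_meta["compartment"].to_numpy(),
            "fold_change": fc,
            "t_statistic": t,
            "p_value": p,
            "significant_05": p < 0.05,
            "significant_01": p < 0.01,
            "significant_bonferroni": bonf,
        }
    ).set_index("analyte_id")
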