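"""Patient heterogeneity and protein co-regulation structure.

Hierarchical clustering of patients by their signature expression uses
average (UPGMA) linkage on the Pearson correlation distance d = 1 − r; the
clustering itself is unsupervised and is *evaluated* against the known group
labels (misclassification count under majority mapping).

Correlation networks are built per group over the signature analytes: every
pairwise Pearson correlation with p < alpha becomes an edge, and nodes with
at least four significant correlations are flagged as hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .feature_selection import Signature
from .io import AnalyteTable
from .univariate import pearson

logger = logging.getLogger(__name__)

HUB_DEGREE = 4


def _signature_ids(signature) -> list[str]:
    if isinstance(signature, Signature):
        return list(signature.analyte_ids)
    return list(signature)


@dataclass
class Dendrogram:
    """Average-linkage tree over samples in correlation distance."""

    linkage: np.ndarray
    leaf_order: list[str]
    sample_ids: list[str]
    cluster_assignment: pd.Series  # flat clusters at the requested cut
    n_clusters: int
    misclassified: int | None = None  # vs known labels under majority mapping
    analyte_linkage: np.ndarray | None = None
    analyte_order: list[str] | None = None


def _majority_misclassification(clusters: np.ndarray, labels: np.ndarray) -> int:
    """Samples whose label differs from their cluster's majority label."""
    wrong = 0
    for c in np.unique(clusters):
        sub = labels[clusters == c]
        values, counts = np.unique(sub, return_counts=True)
        wrong += int(len(sub) - counts.max())
        del values
    return wrong


def hcluster(
    table: AnalyteTable,
    signature,
    n_clusters: int = 2,
    labels: pd.Series | None = None,
) -> Dendrogram:
    """Cluster samples by their (autoscaled) signature expression profiles.

    ``labels`` defaults to the table's group column; pass ``labels=False`` to
    skip the evaluation step.
    """
    ids = _signature_ids(signature)
    sub = table.subset_analytes(ids)
    X = sub.values.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    dist = pdist(X, metric="correlation")  # 1 - Pearson r between profiles
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")

    mis = None
    if labels is None:
        labels = sub.sample_meta["group"]
    if labels is not False:
        mis = _majority_misclassification(flat, np.asarray(labels))

    a_link = a_order = None
    if len(ids) >= 3:
        a_dist = pdist(X.T, metric="correlation")
        a_link = hierarchy.linkage(a_dist, method="average")
        a_order = [ids[i] for i in hierarchy.leaves_list(a_link)]

    return Dendrogram(
        linkage=Z,
        leaf_order=[sub.sample_ids[i] for i in order],
        sample_ids=sub.sample_ids,
        cluster_assignment=pd.Series(flat, index=sub.values.index, name="cluster"),
        n_clusters=n_clusters,
        misclassified=mis,
        analyte_linkage=a_link,
        analyte_order=a_order,
    )


class SignatureClustering:
    """Estimator-style wrapper over :func:`hcluster`.

    ``fit(table)`` stores the dendrogram; ``labels_`` holds the flat cluster
    assignment at the requested cut.
    """

    def __init__(self, signature, n_clusters: int = 2):
        self.signature = signature
        self.n_clusters = n_clusters

    def fit(self, table: AnalyteTable, labels=None):
        self.dendrogram_ = hcluster(table, self.signature, self.n_clusters, labels)
        self.labels_ = self.dendrogram_.cluster_assignment.to_numpy()
        return self

    def get_params(self, deep: bool = True):
        return {"signature": self.signature, "n_clusters": self.n_clusters}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


# ---------------------------------------------------------------------------
# correlation networks
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    """Significance-filtered pairwise Pearson network over a signature."""

    graph: nx.Graph
    group: str
    alpha: float
    excluded_analytes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def hub_ids(self) -> list[str]:
        return [n for n, d in self.graph.degree() if d >= HUB_DEGREE]

    @property
    def edge_r(self) -> np.ndarray:
        return np.asarray([d["r"] for _, _, d in self.graph.edges(data=True)], dtype=float)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"analyte_a": a, "analyte_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "r", "p"])


def corr_network(
    table: AnalyteTable,
    signature,
    group: str,
    alpha: float = 0.05,
) -> CorrelationNetwork:
    """Within-group Pearson network over the signature analytes.

    Edges keep only correlations with p < alpha; the p-values come from the
    same Pearson routine used everywhere else in the package.
    """
    ids = _signature_ids(signature)
    values = table.subset_analytes(ids).group_values(group)
    if len(values) < 4:
        raise ValueError(f"need at least 4 samples in group {group!r}")

    excluded = [a for a in ids if values[a].std() == 0]
    if excluded:
        logger.warning("excluding constant analyte(s) from network: %s", excluded[:10])
    kept = [a for a in ids if a not in set(excluded)]

    g = nx.Graph()
    g.add_nodes_from(kept)
    arr = values[kept].to_numpy(dtype=float)
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            r, p = pearson(arr[:, i], arr[:, j])
            if p < alpha:
                g.add_edge(kept[i], kept[j], r=r, p=p)
    return CorrelationNetwork(graph=g, group=group, alpha=alpha, excluded_analytes=excluded)


@dataclass
class NetworkComparison:
    edges_a: int
    edges_b: int
    hubs_a: int
    hubs_b: int
    mean_abs_r_a: float
    mean_abs_r_b: float
    t_statistic: float | None
    p_value: float | None


def compare_networks(net_a: CorrelationNetwork, net_b: CorrelationNetwork) -> NetworkComparison:
    """Contrast two group networks: edge and hub counts plus a pooled
    two-sample t-test on the absolute correlation strengths of their edges."""
    nodes_a = set(net_a.graph.nodes) | set(net_a.excluded_analytes)
    nodes_b = set(net_b.graph.nodes) | set(net_b.excluded_analytes)
    if nodes_a != nodes_b:
        raise ValueError("networks must be built over the same analyte set")
    ra = np.abs(net_a.edge_r)
    rb = np.abs(net_b.edge_r)
    t = p = None
    if len(ra) >= 2 and len(rb) >= 2:
        if np.ptp(np.concatenate([ra, rb])) == 0:
            t, p = 0.0, 1.0
        else:
            from scipy import stats as _st

            t_res = _st.ttest_ind(ra, rb, equal_var=True)
            t, p = float(t_res.statistic), float(t_res.pvalue)
    return NetworkComparison(
        edges_a=net_a.n_edges,
        edges_b=net_b.n_edges,
        hubs_a=len(net_a.hub_ids),
        hubs_b=len(net_b.hub_ids),
        mean_abs_r_a=float(ra.mean()) if len(ra) else float("nan"),
        mean_abs_r_b=float(rb.mean()) if len(rb) else float("nan"),
        t_statistic=t,
        p_value=p,
    )
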