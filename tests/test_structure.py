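"""Hierarchical clustering of patients and group correlation networks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from progsig import (
    CohortConfig,
    autoscale,
    compare_networks,
    corr_network,
    generate_cohort,
    hcluster,
)
from progsig.structure import _majority_misclassification
from progsig.univariate import pearson

from conftest import make_table


def _cluster_table(seed=0):
    cfg = CohortConfig(
        n_prog=30, n_nonprog=20, p_blood=80, p_bal=5, k_signature=20, effect_size=1.5, seed=seed
    )
    coh = generate_cohort(cfg)
    truth = coh.truth
    panel = truth.signature_analytes + [a for ids in truth.subgroup_analytes.values() for a in ids]
    panel = [a for a in panel if a in coh.blood_tables[0].values.columns]
    scaled, _ = autoscale(coh.blood_tables[0].subset_analytes(panel))
    return scaled, coh


class TestHCluster:
    def test_identical_samples_merge_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 10))
        X[3] = X[1]
        dg = hcluster(make_table(X), [f"A{j:03d}" for j in range(10)], n_clusters=2, labels=False)
        first_merge = dg.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {1, 3}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_nondecreasing(self):
        scaled, _ = _cluster_table()
        dg = hcluster(scaled, scaled.analyte_ids, n_clusters=4)
        assert np.all(np.diff(dg.linkage[:, 2]) >= -1e-12)
        assert len(dg.leaf_order) == scaled.n_samples

    def test_planted_subgroups_recovered_at_four_clusters(self):
        scaled, coh = _cluster_table(seed=3)
        dg = hcluster(scaled, scaled.analyte_ids, n_clusters=4)
        truth_labels = [
            0 if g == "non_progressor" else 1 + coh.truth.subgroup_labels[s]
            for s, g in zip(scaled.sample_meta["subject_id"], scaled.sample_meta["group"])
        ]
        ari = adjusted_rand_score(truth_labels, dg.cluster_assignment.to_numpy())
        assert ari >= 0.7
        # two-cluster cut separates mostly by progression status
        dg2 = hcluster(scaled, scaled.analyte_ids, n_clusters=2)
        assert dg2.misclassified <= 10

    def test_majority_misclassification_hand_example(self):
        clusters = np.array([1, 1, 1, 2, 2, 2])
        labels = np.array(["a", "a", "b", "b", "b", "a"])
        assert _majority_misclassification(clusters, labels) == 2

    def test_too_few_samples(self):
        t = make_table(np.random.default_rng(1).standard_normal((2, 4)))
        with pytest.raises(ValueError, match="3 samples"):
            hcluster(t, t.analyte_ids, labels=False)


class TestCorrNetwork:
    def test_linear_copy_gives_perfect_edge(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        X[:, 2] = 2.0 * X[:, 0] + 1.0
        t = make_table(X, groups=["progressor"] * 20)
        net = corr_network(t, t.analyte_ids, group="progressor")
        assert net.graph.has_edge("A000", "A002")
        assert net.graph.edges["A000", "A002"]["r"] == pytest.approx(1.0)

    def test_null_edge_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 25))
        t = make_table(X, groups=["progressor"] * 40)
        net = corr_network(t, t.analyte_ids, group="progressor", alpha=0.05)
        m_pairs = 25 * 24 / 2
        assert net.n_edges / m_pairs < 0.12

    def test_star_factor_center_is_hub(self):
        rng = np.random.default_rng(4)
        n = 40
        center = rng.standard_normal(n)
        X = np.column_stack(
            [center] + [0.8 * center + 0.4 * rng.standard_normal(n) for _ in range(5)]
            + [rng.standard_normal(n) for _ in range(4)]
        )
        t = make_table(X, groups=["progressor"] * n)
        net = corr_network(t, t.analyte_ids, group="progressor")
        assert "A000" in net.hub_ids

    def test_edge_pvalues_match_pearson_code_path(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 4))
        X[:, 1] += X[:, 0]
        t = make_table(X, groups=["progressor"] * 15)
        net = corr_network(t, t.analyte_ids, group="progressor")
        for a, b, d in net.graph.edges(data=True):
            r, p = pearson(t.values[a], t.values[b])
            assert d["r"] == r and d["p"] == p

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 6))
        X[:, 3] += X[:, 1]
        t = make_table(X, groups=["progressor"] * 20)
        ids = t.analyte_ids
        net1 = corr_network(t, ids, group="progressor")
        net2 = corr_network(t, ids[::-1], group="progressor")
        assert set(map(frozenset, net1.graph.edges)) == set(map(frozenset, net2.graph.edges))

    def test_constant_analyte_excluded_with_warning(self):
        X = np.random.default_rng(7).standard_normal((12, 3))
        X[:, 2] = 5.0
        t = make_table(X, groups=["progressor"] * 12)
        net = corr_network(t, t.analyte_ids, group="progressor")
        assert net.excluded_analytes == ["A002"]

    def test_group_too_small(self):
        t = make_table(np.random.default_rng(8).standard_normal((5, 3)), groups=["progressor"] * 3 + ["non_progressor"] * 2)
        with pytest.raises(ValueError, match="at least 4"):
            corr_network(t, t.analyte_ids, group="non_progressor")


class TestCompareNetworks:
    def test_identical_networks(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 8))
        X[:, 1] += X[:, 0]
        X[:, 3] += X[:, 2]
        t = make_table(X, groups=["progressor"] * 25)
        net = corr_network(t, t.analyte_ids, group="progressor")
        res = compare_networks(net, net)
        assert res.edges_a == res.edges_b
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_hand_worked_t_statistic(self):
        from scipy import stats

        a = np.array([0.9, 0.8])
        b = np.array([0.3, 0.3, 0.3])
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert t_ref == pytest.approx(14.7573, abs=1e-3)  # pooled-variance closed form
        assert p_ref < 0.001

    def test_planted_contrast_single_cohort(self, small_cohort, merged_week0):
        sig = small_cohort.truth.signature_analytes
        prog = corr_network(merged_week0, sig, group="progressor")
        nonp = corr_network(merged_week0, sig, group="non_progressor")
        res = compare_networks(nonp, prog)
        assert res.edges_a < res.edges_b  # sparser in non-progressors
        assert res.mean_abs_r_a > res.mean_abs_r_b  # but stronger

    def test_mismatched_analyte_sets_rejected(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.standard_normal((20, 5)), groups=["progressor"] * 20)
        n1 = corr_network(t, t.analyte_ids, group="progressor")
        n2 = corr_network(t, t.analyte_ids[:4], group="progressor")
        with pytest.raises(ValueError, match="same analyte set"):
            compare_networks(n1, n2)
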