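"""NIPALS PLSDA: oracle agreement, VIP identities, orthogonalisation,
prediction rules, cross-validation and classification metrics."""

import numpy as np
import pytest

from progsig import (
    PLSDAClassifier,
    classification_metrics,
    cross_validate,
    fit_plsda,
    orthogonalize,
    roc_curve,
)
from progsig.plsda import StratificationError


def eigen_pls1(X, y, n_lv):
    """Independent PLS1 reference: weights from the eigen-decomposition of
    X'yy'X, with the same deflation scheme."""
    Xd, yd = X.copy(), y.copy()
    W, T, P, q = [], [], [], []
    for _ in range(n_lv):
        M = Xd.T @ np.outer(yd, yd) @ Xd
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * qa
        W.append(w), T.append(t), P.append(p), q.append(qa)
    return np.array(W).T, np.array(T).T, np.array(P).T, np.array(q)


def make_binary(rng, n=24, p=6, delta=1.0):
    X = rng.standard_normal((n, p))
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n - n // 2))
    X[y == "pos", :2] += delta
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    return Xs, y


class TestNipals:
    def test_matches_eigen_decomposition_reference(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            Xs, y = make_binary(np.random.default_rng(seed), n=12, p=6)
            m = fit_plsda(Xs, y, n_lv=3)
            yc = np.where(y == "pos", 1.0, 0.0)
            W, T, P, q = eigen_pls1(Xs, yc - yc.mean(), 3)
            for a in range(3):
                sign = np.sign(W[:, a] @ m.x_weights_[:, a])
                np.testing.assert_allclose(m.x_weights_[:, a], sign * W[:, a], atol=1e-8)
                np.testing.assert_allclose(m.x_scores_[:, a], sign * T[:, a], atol=1e-8)
                np.testing.assert_allclose(m.x_loadings_[:, a], sign * P[:, a], atol=1e-8)
        del rng

    def test_full_rank_predictions_equal_least_squares(self):
        rng = np.random.default_rng(1)
        n, p = 9, 8
        X = rng.standard_normal((n, p))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array(["a", "b"] * 4 + ["a"])
        m = fit_plsda(Xs, y, n_lv=p)
        yc = np.where(y == "b", 1.0, 0.0)
        ols = Xs @ np.linalg.lstsq(Xs, yc - yc.mean(), rcond=None)[0] + yc.mean()
        np.testing.assert_allclose(m.decision_function(Xs), ols, atol=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self):
        Xs, y = make_binary(np.random.default_rng(2), n=30, p=10)
        m = fit_plsda(Xs, y, n_lv=4)
        T = m.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()
        np.testing.assert_allclose(np.linalg.norm(m.x_weights_, axis=0), 1.0, atol=1e-10)

    def test_separable_univariate(self):
        x = np.concatenate([np.full(10, -2.0), np.full(10, 2.0)]) + 0.1 * np.random.default_rng(3).standard_normal(20)
        y = np.array(["lo"] * 10 + ["hi"] * 10)
        m = PLSDAClassifier(n_components=1).fit(x[:, None], y)
        assert (m.predict(x[:, None]) == y).all()

    def test_component_count_validation(self):
        Xs, y = make_binary(np.random.default_rng(4), n=10, p=3)
        with pytest.raises(ValueError, match="n_components"):
            fit_plsda(Xs, y, n_lv=4)

    def test_permuted_labels_lose_lv1_variance(self):
        rng = np.random.default_rng(5)
        Xs, y = make_binary(rng, n=40, p=10, delta=2.0)
        m = fit_plsda(Xs, y, n_lv=1)
        ssy_true = m.ssy_[0]
        null_ssy = []
        for _ in range(20):
            m0 = fit_plsda(Xs, rng.permutation(y), n_lv=1)
            null_ssy.append(m0.ssy_[0])
        assert ssy_true > 1.5 * np.max(null_ssy)
        assert ssy_true > 3 * np.mean(null_ssy)


class TestVIP:
    def test_sum_of_squares_identity(self):
        for seed, p in [(0, 5), (1, 12), (2, 40)]:
            Xs, y = make_binary(np.random.default_rng(seed), n=30, p=p)
            m = fit_plsda(Xs, y, n_lv=2)
            assert np.sum(m.vip_**2) == pytest.approx(p, abs=1e-8)

    def test_planted_predictor_dominates(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 8))
        y = np.where(X[:, 0] > 0, "a", "b")
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        m = fit_plsda(Xs, y, n_lv=2)
        assert m.vip_[0] > 1.5
        assert np.all(m.vip_[1:] < m.vip_[0])


class TestOrthogonalize:
    def _model(self, seed=0, n_lv=3):
        Xs, y = make_binary(np.random.default_rng(seed), n=30, p=8, delta=1.0)
        return fit_plsda(Xs, y, n_lv=n_lv), Xs, y

    def test_predictions_invariant(self):
        m, Xs, y = self._model()
        om = orthogonalize(m)
        np.testing.assert_allclose(m.decision_function(Xs), om.decision_function(Xs), atol=1e-10)
        assert (m.predict(Xs) == om.predict(Xs)).all()

    def test_lv1_concentrates_class_correlation(self):
        m, Xs, y = self._model(seed=1)
        om = orthogonalize(m)
        yc = np.where(y == "pos", 1.0, 0.0)
        before = abs(np.corrcoef(m.x_scores_[:, 0], yc)[0, 1])
        after = abs(np.corrcoef(om.x_scores_[:, 0], yc)[0, 1])
        assert after >= before - 1e-12
        # later LVs are uncorrelated with the class coding
        for a in range(1, om.x_scores_.shape[1]):
            assert abs(np.corrcoef(om.x_scores_[:, a], yc)[0, 1]) < 1e-8

    def test_lv1_sign_orients_first_class_positive(self):
        m, Xs, y = self._model(seed=2)
        om = orthogonalize(m)
        neg_class = om.classes_[0]  # coded 0
        assert om.x_scores_[y == neg_class, 0].mean() > 0

    def test_scores_stay_orthogonal(self):
        m, _, _ = self._model(seed=3)
        om = orthogonalize(m)
        T = om.x_scores_
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8 * np.diag(G).max()

    def test_single_lv_is_identity_with_warning(self, caplog):
        m, Xs, _ = self._model(n_lv=1)
        om = orthogonalize(m)
        np.testing.assert_allclose(om.x_scores_, m.x_scores_)


class TestPredictRule:
    def test_midpoint_tie_goes_to_higher_code(self):
        m = PLSDAClassifier(n_components=1)
        m.classes_ = np.array(["non_progressor", "progressor"])
        m.coef_ = np.zeros(2)
        m.y_mean_ = 0.5  # every score lands exactly on the midpoint
        m.x_means_ = np.zeros(2)
        m.x_sds_ = np.ones(2)
        m._live_cols_ = np.ones(2, dtype=bool)
        m.feature_names_in_ = np.array([0, 1], dtype=object)
        m.n_features_in_ = 2
        pred = m.predict(np.zeros((3, 2)))
        assert (pred == "progressor").all()

    def test_score_monotone_along_lv1_displacement(self):
        Xs, y = make_binary(np.random.default_rng(7), n=30, p=6, delta=1.5)
        m = fit_plsda(Xs, y, n_lv=2)
        direction = m.coef_ / np.linalg.norm(m.coef_)
        base = np.zeros((1, 6))
        scores = [m.decision_function(base + t * direction)[0] for t in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(scores) > 0)

    def test_analyte_count_mismatch(self):
        Xs, y = make_binary(np.random.default_rng(8), n=20, p=6)
        m = fit_plsda(Xs, y, n_lv=2)
        with pytest.raises(ValueError, match="analytes"):
            m.predict(Xs[:, :4])


class TestCrossValidate:
    def test_fold_sizes_five_to_six_at_n59(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((59, 10))
        y = np.array(["progressor"] * 34 + ["non_progressor"] * 25)
        X[y == "progressor", 0] += 3.0
        res = cross_validate(X, y, k=10, seed=0)
        sizes = np.bincount(res.fold_assignment, minlength=10)
        assert sizes.min() == 5 and sizes.max() == 6
        assert res.pooled_cv_accuracy == pytest.approx(np.mean(res.per_sample_prediction == y))

    def test_separable_cohort_high_accuracy(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 10))
        y = np.array(["a"] * 30 + ["b"] * 30)
        X[y == "b"] += 3.0 / np.sqrt(10)
        res = cross_validate(X, y, k=10, seed=1)
        assert res.pooled_cv_accuracy >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 10))
        accs = [
            cross_validate(X, rng.permutation(["a"] * 30 + ["b"] * 30), k=10, seed=s).pooled_cv_accuracy
            for s in range(5)
        ]
        assert np.mean(accs) < 0.65

    def test_singleton_class_raises_stratification_error(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 4))
        y = np.array(["a"] * 19 + ["b"])
        with pytest.raises(StratificationError):
            cross_validate(X, y, k=10, seed=0)


class TestMetricsAndROC:
    def test_hand_confusion_counts(self):
        truth = ["p"] * 4 + ["n"] * 4
        pred = ["p", "p", "p", "n", "p", "p", "n", "n"]
        m = classification_metrics(pred, truth, positive_class="p")
        assert (m.tp, m.fn, m.fp, m.tn) == (3, 1, 2, 2)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.5)
        assert m.ppv == pytest.approx(0.6)
        assert m.npv == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(5 / 8)

    def test_perfect_and_inverted(self):
        truth = ["p", "p", "n", "n"]
        perfect = classification_metrics(truth, truth, "p")
        assert perfect.accuracy == perfect.sensitivity == perfect.specificity == 1.0
        inverted = classification_metrics(["n", "n", "p", "p"], truth, "p")
        assert inverted.sensitivity == 0.0 and inverted.specificity == 0.0

    def test_absent_class_flagged_not_zeroed(self):
        m = classification_metrics(["p", "p"], ["p", "p"], positive_class="p")
        assert "specificity" in m.undefined and np.isnan(m.specificity)

    def test_roc_perfect_random_reversed(self):
        rng = np.random.default_rng(13)
        truth = np.array(["n"] * 50 + ["p"] * 50)
        perfect = np.concatenate([np.zeros(50), np.ones(50)])
        assert roc_curve(perfect, truth, "p").auc == 1.0
        rand = rng.standard_normal(100)
        auc = roc_curve(rand, truth, "p").auc
        assert roc_curve(-rand, truth, "p").auc == pytest.approx(1 - auc)
        assert np.all(np.diff(roc_curve(rand, truth, "p").fpr) >= 0)

    def test_roc_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], ["p", "p"])
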