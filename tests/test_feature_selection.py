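"""LASSO coordinate descent, the CV-selected signature, and VIP selection."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso as SkLasso

from progsig import PLSDAClassifier, lasso_cv, lasso_fit, vip_select
from progsig.feature_selection import EmptySignatureError, LassoSelector, lambda_grid, lasso_path


def random_instance(rng, n=20, p=6, snr=1.0):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = rng.standard_normal(p) * snr
    y = X @ beta + rng.standard_normal(n)
    return X, y - y.mean()


class TestLassoFit:
    def test_zero_penalty_recovers_least_squares(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=40, p=5)
        beta = lasso_fit(X, y, 0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_lambda_max_gives_exact_zero(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng)
        lam_max = np.abs(X.T @ y).max() / len(y)
        assert np.all(lasso_fit(X, y, lam_max) == 0.0)
        assert np.all(lasso_fit(X, y, 2 * lam_max) == 0.0)

    def test_matches_sklearn_coordinate_descent(self):
        # same objective (1/2n)||y-Xb||^2 + lam ||b||_1 as sklearn's Lasso
        rng = np.random.default_rng(2)
        for _ in range(5):
            X, y = random_instance(rng, n=25, p=8)
            lam = 0.1 * np.abs(X.T @ y).max() / len(y)
            ours = lasso_fit(X, y, lam, tol=1e-10)
            ref = SkLasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=100000).fit(X, y).coef_
            np.testing.assert_allclose(ours, ref, atol=1e-7)

    def test_negative_penalty_and_nonfinite_rejected(self):
        X, y = random_instance(np.random.default_rng(3))
        with pytest.raises(ValueError, match="nonnegative"):
            lasso_fit(X, y, -0.1)
        X2 = X.copy()
        X2[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            lasso_fit(X2, y, 0.1)

    def test_l1_norm_monotone_along_path(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng, n=30, p=10)
        grid = lambda_grid(X, y, n_lambdas=40)
        betas = lasso_path(X, y, grid)
        norms = np.abs(betas).sum(axis=1)
        assert np.all(np.diff(norms) >= -1e-8)  # nonincreasing in lambda


class TestLassoCV:
    def test_planted_linear_model_recovered(self):
        rng = np.random.default_rng(5)
        n, p = 100, 30
        X = rng.standard_normal((n, p))
        y = 2.0 * X[:, 0] - 1.5 * X[:, 3] + 1.0 * X[:, 7] + 0.3 * rng.standard_normal(n)
        sig = lasso_cv(X, y, k=10, seed=0)
        assert {0, 3, 7} <= set(sig.analyte_ids)
        assert sig.lambda_selected > 0
        assert len(sig.weights) == len(sig.analyte_ids)

    def test_permuted_labels_give_empty_or_tiny_signature(self):
        rng = np.random.default_rng(6)
        n, p = 60, 40
        X = rng.standard_normal((n, p))
        empty_or_tiny = 0
        for seed in range(5):
            y = rng.permutation([0.0] * 30 + [1.0] * 30)
            sel = LassoSelector(cv=10, random_state=seed).fit(X, y)
            mse = sel.mse_path_
            assert mse.min() > 0.15  # CV error stays near var(y) = 0.25
            empty_or_tiny += int(sel.support_.sum() <= 3)
        assert empty_or_tiny >= 4

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 20))
        y = X[:, 2] + 0.5 * rng.standard_normal(50)
        s1 = lasso_cv(X, y, k=10, seed=3)
        s2 = lasso_cv(X, y, k=10, seed=3)
        assert s1.analyte_ids == s2.analyte_ids
        np.testing.assert_array_equal(s1.weights, s2.weights)

    def test_leave_one_out_boundary(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((15, 5))
        y = X[:, 1] + 0.2 * rng.standard_normal(15)
        sig = lasso_cv(X, y, k=15, seed=0)
        assert 1 in sig.analyte_ids

    def test_fold_assignment_recorded_and_balanced(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((59, 10))
        y = np.array([0.0] * 34 + [1.0] * 25)
        sel = LassoSelector(cv=10, random_state=1).fit(X, y + X[:, 0])
        sizes = np.bincount(sel.fold_assignment_, minlength=10)
        assert sizes.min() >= 5 and sizes.max() <= 6


class TestVIPSelect:
    def _fitted_model(self, seed=0, p=12):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, p))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(40) > 0, "a", "b")
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        return PLSDAClassifier(n_components=2, scale=False).fit(Xs, y)

    def test_cutoff_zero_selects_everything(self):
        m = self._fitted_model()
        assert len(vip_select(m, cutoff=0.0)) == 12

    def test_single_analyte_model_has_vip_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)[:, None]
        y = np.where(x.ravel() > 0, "a", "b")
        m = PLSDAClassifier(n_components=1, scale=True).fit(x, y)
        assert m.vip_ == pytest.approx([1.0])
        assert vip_select(m, cutoff=1.0).analyte_ids == [0]

    def test_selected_count_and_independent_recomputation(self):
        m = self._fitted_model(seed=2, p=29)
        sig = vip_select(m, cutoff=1.0)
        assert 0 < len(sig) < 29
        # independent VIP recomputation from stored weights and SSY
        W, ssy = m.x_weights_, m.ssy_
        w_unit = W / np.linalg.norm(W, axis=0)
        vip_ref = np.sqrt(29 * (w_unit**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(np.sort(sig.weights)[::-1], np.sort(vip_ref[vip_ref >= 1])[::-1], atol=1e-10)

    def test_impossible_cutoff_raises(self):
        with pytest.raises(EmptySignatureError):
            vip_select(self._fitted_model(), cutoff=10.0)
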