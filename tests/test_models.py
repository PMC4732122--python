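"""Regression backends and CV harness, cross-checked against sklearn and
brute-force oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirselect import models
from nirselect._kernels import pls1_cv_sse, pls1_prefix_sse


def _sklearn_pls_coef(X, y, lv):
    m = PLSRegression(n_components=lv, scale=False).fit(X, y)
    return m.coef_.ravel(), float(m.intercept_.ravel()[0])


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert models.rmse(y, y) == 0.0
        assert models.pearson_r(y, y) == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([1.0, 2.0, 5.0])
        assert models.pearson_r(-y, y) == pytest.approx(-1.0)

    def test_loo_rmse_matches_hand_oracle(self):
        """LOO CV of a one-variable OLS on 5 points vs explicit recomputation."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])[:, None]
        y = np.array([0.1, 0.9, 2.2, 2.9, 5.3])
        sse = 0.0
        for i in range(5):
            keep = np.arange(5) != i
            A = np.column_stack([np.ones(4), x[keep]])
            beta, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
            pred = beta[0] + beta[1] * x[i, 0]
            sse += (pred - y[i]) ** 2
        oracle = np.sqrt(sse / 5)
        cv = models.cross_validate(models.ModelSpec(kind="mlr"), x, y, folds="loo")
        assert cv.best_rmsecv == pytest.approx(oracle, abs=1e-12)


class TestFolds:
    def test_partition_depends_only_on_arguments(self):
        a = models.make_folds(20, 5, seed=3)
        b = models.make_folds(20, 5, seed=3)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, models.make_folds(20, 5, seed=4))
        counts = np.bincount(a)
        assert counts.max() - counts.min() <= 1

    def test_loo_gives_singletons(self):
        assert set(np.bincount(models.make_folds(7, "loo"))) == {1}

    def test_loo_rmsecv_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(12, 4))
        y = X @ rng.normal(size=4) + rng.normal(0, 0.1, 12)
        perm = rng.permutation(12)
        a = models.select_pls_lv(X, y, 3, folds="loo").rmsecv
        b = models.select_pls_lv(X[perm], y[perm], 3, folds="loo").rmsecv
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestMLR:
    def test_exact_linear_system(self, rng):
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7
        model = models.MLRModel().fit(X, y)
        assert models.rmse(model.predict(X), y) < 1e-10

    def test_line_through_two_points(self):
        model = models.MLRModel().fit(np.array([[0.0], [2.0], [4.0]]),
                                      np.array([1.0, 5.0, 9.0]))
        assert model.intercept_ == pytest.approx(1.0)
        assert model.coef_[0] == pytest.approx(2.0)

    def test_underdetermined_rejected(self, rng):
        X = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="n=5, p=5"):
            models.MLRModel().fit(X, rng.normal(size=5))

    def test_rank_deficient_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(ValueError, match="rank"):
            models.MLRModel().fit(X, rng.normal(size=10))


class TestPLS:
    def test_single_latent_direction_no_noise(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=8))
        y = 2.0 * t
        cv = models.select_pls_lv(X, y, max_lv=3, folds=5)
        assert cv.rmsecv[0] < 1e-8

    def test_full_rank_pls_equals_mlr(self, rng):
        """With all latent variables PLS reproduces OLS predictions."""
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        pls = models.PLSModel(5).fit(X, y)
        mlr = models.MLRModel().fit(X, y)
        np.testing.assert_allclose(pls.predict(X), mlr.predict(X), atol=1e-8)

    def test_coefficient_representation_identity(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.1, 25)
        model = models.PLSModel(4).fit(X, y)
        pred = X @ model.coef_ + model.intercept_
        np.testing.assert_allclose(pred, model.predict(X), atol=1e-10)

    @pytest.mark.parametrize("lv", [1, 2, 4])
    def test_matches_sklearn_nipals(self, rng, lv):
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.5, 30)
        model = models.PLSModel(lv).fit(X, y)
        sk = PLSRegression(n_components=lv, scale=False).fit(X, y)
        np.testing.assert_allclose(model.coef_, sk.coef_.ravel(), atol=1e-8)
        np.testing.assert_allclose(model.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_collapse_recorded(self, rng):
        t = rng.normal(size=15)
        X = np.outer(t, rng.normal(size=6))  # rank 1
        model = models.PLSModel(4).fit(X, 3 * t)
        assert model.n_components_ == 1


class TestKernels:
    """The compiled CV kernels against a brute-force sklearn loop."""

    def _brute_cv(self, X, y, fold_id, max_lv):
        n = y.size
        sse = np.zeros(max_lv)
        for lv in range(1, max_lv + 1):
            for f in range(fold_id.max() + 1):
                tr = fold_id != f
                m = PLSRegression(n_components=lv, scale=False).fit(X[tr], y[tr])
                pred = m.predict(X[~tr]).ravel()
                sse[lv - 1] += np.sum((pred - y[~tr]) ** 2)
        return sse

    def test_cv_sse_matches_sklearn(self, rng):
        X = rng.normal(size=(24, 9))
        y = X @ rng.normal(size=9) + rng.normal(0, 0.3, 24)
        fold_id = models.make_folds(24, 4, seed=0)
        fast = pls1_cv_sse(np.ascontiguousarray(X), y, fold_id, 4, 5)
        brute = self._brute_cv(X, y, fold_id, 5)
        np.testing.assert_allclose(fast, brute, rtol=1e-8)

    def test_prefix_sse_matches_sklearn(self, rng):
        X = rng.normal(size=(18, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.3, 18)
        fold_id = models.make_folds(18, 3, seed=1)
        fast = pls1_prefix_sse(np.ascontiguousarray(X), y, fold_id, 3, 4)
        for t in range(1, 7):
            brute = self._brute_cv(X[:, :t], y, fold_id, min(t, 4))
            np.testing.assert_allclose(fast[t - 1, : min(t, 4)], brute, rtol=1e-8)


class TestLSSVM:
    def test_interpolation_limit(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = models.LSSVMModel(gamma=1e9, sigma2=1.0).fit(X, y)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-3

    def test_duplicate_points_remain_solvable(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]])
        y = np.array([0.5, 0.5, 1.0, 2.0])
        model = models.LSSVMModel(gamma=10.0, sigma2=1.0).fit(X, y)
        assert np.all(np.isfinite(model.predict(X)))

    def test_grid_tuning_matches_brute_force_loo(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=12)
        gammas, sigma2s = [1.0, 10.0, 100.0], [0.5, 1.0, 2.0]
        cv = models.tune_lssvm(X, y, gammas, sigma2s, folds="loo")
        brute = {}
        for g in gammas:
            for s in sigma2s:
                sse = 0.0
                for i in range(12):
                    keep = np.arange(12) != i
                    m = models.LSSVMModel(g, s).fit(X[keep], y[keep])
                    sse += float((m.predict(X[i : i + 1])[0] - y[i]) ** 2)
                brute[(g, s)] = np.sqrt(sse / 12)
        best_brute = min(brute.values())
        assert cv.best_rmsecv == pytest.approx(best_brute, abs=1e-10)
        assert brute[cv.best_candidate] == pytest.approx(best_brute, abs=1e-10)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            models.LSSVMModel(gamma=0.0, sigma2=1.0)
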