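import numpy as np
import pytest
from scipy import stats

from lexepi.prediction import (
    PipelineConfig,
    assign_folds,
    compare_models,
    crossval_predict,
    evaluate,
    ols_fit,
    pca_reduce,
    ridge_fit,
    screen_features,
)


class TestOlsFit:
    def test_exact_linear(self):
        x = np.arange(10.0)
        fit = ols_fit(x[:, None], 2 * x)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_orthogonal_outcome(self):
        # y has zero covariance with the single column
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([1.0, 1.0, 3.0, 3.0])
        fit = ols_fit(X, y)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        fit = ols_fit(X, y)
        D = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)  # independent brute force
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], beta, atol=1e-10
        )
        resid = y - D @ beta
        sigma2 = resid @ resid / (50 - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))[1:]
        np.testing.assert_allclose(fit.std_errors, se, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(40, 4))
        fit = ols_fit(X, rng.normal(size=40))
        for j in range(4):
            dot = abs(fit.residuals @ X[:, j])
            assert dot < 1e-8 * np.linalg.norm(fit.residuals) * np.linalg.norm(X[:, j])

    def test_rank_deficiency_error(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(X, rng.normal(size=30))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones((3, 3)), np.ones(3))


class TestRidgeFit:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        ridge = ridge_fit(X, y, 0.0)
        ols = ols_fit(X, y)
        np.testing.assert_allclose(ridge.coefficients, ols.coefficients, atol=1e-8)
        assert ridge.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        big = ridge_fit(X, y, 1e9)
        ols = ols_fit(X, y)
        assert np.linalg.norm(big.coefficients) < 1e-3 * np.linalg.norm(
            ols.coefficients
        )

    def test_single_feature_closed_form(self, rng):
        # x pre-standardized (mean 0, sample sd 1) so the internal scaling
        # is the identity and the hand formula applies directly
        x = rng.normal(size=25)
        x = (x - x.mean()) / x.std(ddof=1)
        y = rng.normal(size=25)
        yc = y - y.mean()
        expected = (x @ yc) / (x @ x + 1.0)
        fit = ridge_fit(x[:, None], y, 1.0)
        assert fit.coefficients[0] == pytest.approx(expected, abs=1e-10)

    def test_coefficient_norm_non_increasing_in_lambda(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        norms = [
            np.linalg.norm(ridge_fit(X, y, lam).coefficients)
            for lam in (0.0, 1.0, 10.0, 100.0, 1000.0, 1e4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            ridge_fit(rng.normal(size=(10, 2)), rng.normal(size=10), -1.0)


class TestScreenFeatures:
    def test_constant_column_always_dropped(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.normal(size=30)
        kept = screen_features(X, y, 0.0, alpha=100.0)
        assert 0 not in kept

    def test_permissive_alpha_keeps_all_nonconstant(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        kept = screen_features(X, y, 0.0, alpha=5.0)  # p <= 5/5 = 1
        assert list(kept) == [0, 1, 2, 3, 4]

    def test_signal_column_recovered(self):
        # 100 noise columns + 1 copy of y: at alpha=0.05 exactly the copy
        # should survive in the vast majority of runs
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            y = r.normal(size=80)
            X = np.column_stack([r.normal(size=(80, 100)), y])
            kept = screen_features(X, y, 0.0, alpha=0.05)
            if list(kept) == [100]:
                hits += 1
        assert hits >= 36  # > 90% of seeded runs

    def test_everything_removed_raises(self):
        X = np.ones((20, 3))
        with pytest.raises(ValueError):
            screen_features(X, np.arange(20.0), 0.0, alpha=60.0)


class TestPcaReduce:
    def test_full_fraction_is_lossless(self, rng):
        X = rng.normal(size=(20, 5))
        T, _, rotation = pca_reduce(X, X, 1.0)
        recon = T @ rotation.T + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_rank_one_needs_single_component(self, rng):
        u = rng.normal(size=30)
        X = np.outer(u, [1.0, 2.0, 3.0])
        T, _, _ = pca_reduce(X, X, 0.5)
        assert T.shape[1] == 1

    def test_explained_variance_matches_eigenvalues(self, rng):
        X = rng.normal(size=(30, 10))
        from sklearn.decomposition import PCA

        pca = PCA(svd_solver="full").fit(X)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(pca.explained_variance_, eigvals, atol=1e-10)

    def test_apply_uses_train_centering(self, rng):
        X_train = rng.normal(size=(25, 4))
        X_apply = rng.normal(loc=10.0, size=(5, 4))
        _, T_apply, rotation = pca_reduce(X_train, X_apply, 1.0)
        expected = (X_apply - X_train.mean(axis=0)) @ rotation
        np.testing.assert_allclose(T_apply, expected, atol=1e-10)


class TestAssignFolds:
    def test_deterministic(self):
        np.testing.assert_array_equal(assign_folds(53, 10, 3), assign_folds(53, 10, 3))

    def test_balanced_partition(self):
        ids = assign_folds(53, 10, 0)
        sizes = np.bincount(ids, minlength=10)
        assert sizes.sum() == 53
        assert sizes.max() - sizes.min() <= 1


class TestCrossvalPredict:
    def test_recovers_exact_linear_signal(self, rng):
        X = rng.normal(size=(100, 2))
        y = 3 * X[:, 0] - 2 * X[:, 1] + 5
        config = PipelineConfig(ridge_lambda=0.0, screen_alpha=10.0,
                                pca_variance_fraction=1.0, n_folds=5, seed=0)
        result = crossval_predict(X, y, config)
        assert result.pooled_r > 0.999

    def test_null_features_give_near_zero_r(self, rng):
        X = rng.normal(size=(200, 50))
        y = rng.normal(size=200)
        config = PipelineConfig(ridge_lambda=1000.0, screen_alpha=60.0, seed=1)
        result = crossval_predict(X, y, config)
        assert abs(result.pooled_r) < 0.2

    def test_controls_only_recovers_generating_r(self, rng):
        n = 400
        controls = rng.normal(size=(n, 3))
        signal = controls @ np.array([1.0, -0.5, 0.25])
        noise = rng.normal(size=n)
        y = signal + noise
        generating_r = np.std(signal) / np.sqrt(np.var(signal) + 1.0)
        config = PipelineConfig(n_folds=10, seed=2)
        result = crossval_predict(None, y, config, controls=controls)
        assert result.pooled_r == pytest.approx(generating_r, abs=0.1)

    def test_combined_degrades_gracefully_to_controls(self, rng):
        n = 500
        controls = rng.normal(size=(n, 3))
        y = controls @ np.array([1.0, 0.5, -0.5]) + rng.normal(size=n)
        X = rng.normal(size=(n, 30))  # zero-signal language features
        config = PipelineConfig(seed=3)
        combined = crossval_predict(X, y, config, controls=controls)
        controls_only = crossval_predict(None, y, config, controls=controls)
        assert abs(combined.pooled_r - controls_only.pooled_r) < 0.05

    def test_leakage_guard_permuting_heldout_outcome(self, rng):
        X = rng.normal(size=(80, 10))
        y = X[:, 0] + rng.normal(size=80)
        config = PipelineConfig(ridge_lambda=10.0, screen_alpha=60.0,
                                n_folds=4, seed=4)
        base = crossval_predict(X, y, config)
        fold = 2
        mask = base.fold_ids == fold
        y_perm = y.copy()
        y_perm[mask] = rng.permutation(y[mask])
        perturbed = crossval_predict(X, y_perm, config)
        np.testing.assert_allclose(
            perturbed.predictions[mask], base.predictions[mask], atol=1e-12
        )

    def test_fold_invariants(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        config = PipelineConfig(ridge_lambda=1.0, screen_alpha=60.0,
                                n_folds=5, seed=5)
        result = crossval_predict(X, y, config)
        sizes = np.bincount(result.fold_ids, minlength=5)
        assert (sizes > 0).all() and sizes.max() - sizes.min() <= 1

    def test_requires_some_features(self, rng):
        with pytest.raises(ValueError):
            crossval_predict(None, rng.normal(size=50), PipelineConfig(n_folds=5))


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=20)
        r, mae = evaluate(y, y)
        assert r == pytest.approx(1.0) and mae == 0.0

    def test_anticorrelated(self, rng):
        y = rng.normal(size=20)
        r, _ = evaluate(-y, y)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        r, mae = evaluate(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        assert r == pytest.approx(
            (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc)), abs=1e-12
        )
        assert mae == pytest.approx(np.mean(np.abs(a - b)), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareModels:
    def test_identical_errors_raise(self):
        with pytest.raises(ValueError, match="zero-variance"):
            compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            compare_models([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_scipy_on_random_data(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        t, p = compare_models(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_power_simulation(self):
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            b = r.normal(size=100)
            a = b + r.normal(0.5, 1.0, size=100)
            _, p = compare_models(a, b)
            rejections += p < 0.05
        assert rejections >= 198  # > 99% power
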