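import numpy as np
import pytest

from careact import (
    classify,
    compute_scatter,
    cross_validate,
    fit_mda,
    make_gaussian_patterns,
    regularize_within,
    select_lambda,
)
from careact.mda import shrink_covariance, _class_covariances


class TestScatter:
    def test_hand_arithmetic_two_classes(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        S_B, S_W, info = compute_scatter(X, y)
        assert S_B[0, 0] == pytest.approx(4.0)  # 2*(0-1)^2 + 2*(2-1)^2
        assert S_W[0, 0] == pytest.approx(0.0)
        assert info["global_mean"][0] == pytest.approx(1.0)

    def test_identical_samples_zero_scatter(self):
        X = np.ones((6, 3))
        y = ["a"] * 3 + ["b"] * 3
        S_B, S_W, _ = compute_scatter(X, y)
        assert np.allclose(S_B, 0) and np.allclose(S_W, 0)

    def test_total_scatter_decomposition(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.choice(["a", "b", "c"], size=30)
        S_B, S_W, _ = compute_scatter(X, y)
        R = X - X.mean(axis=0)
        S_T = R.T @ R
        assert np.trace(S_B) + np.trace(S_W) == pytest.approx(np.trace(S_T))

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            compute_scatter(np.zeros((3, 2)), ["a", "a", "b"])


class TestRegularization:
    def test_lambda_one_gives_identity(self, rng):
        cov = rng.normal(size=(4, 4))
        cov = cov @ cov.T
        out = shrink_covariance(cov, 1.0, scale_aware=False)
        assert np.allclose(out, np.eye(4))

    def test_lambda_zero_reproduces_sw(self, rng):
        X = rng.normal(size=(24, 6))
        y = rng.choice(["a", "b", "c"], size=24)
        _S_B, S_W, info = compute_scatter(X, y)
        covs = _class_covariances(X, y, info["classes"])
        assert np.allclose(regularize_within(covs, 0.0, info["n_i"]), S_W)

    def test_eigenvalue_floor_on_rank_deficient_cov(self):
        v = np.array([1.0, 1.0, 0.0])
        cov = np.outer(v, v)  # rank 1
        out = shrink_covariance(cov, 0.5, scale_aware=False)
        assert np.linalg.eigvalsh(out).min() >= 0.5 - 1e-12

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            shrink_covariance(np.eye(2), 1.5)


class TestFit:
    def test_two_class_direction_matches_fisher(self):
        from careact.validation import eigensolver_agreement

        res = eigensolver_agreement(seed=3)
        assert res["two_class_fisher_cosine"] > 1 - 1e-8

    def test_eigenpairs_match_dense_solver(self):
        from careact.validation import eigensolver_agreement

        res = eigensolver_agreement(seed=5)
        assert res["max_rel_eigenvalue_error"] < 1e-8
        assert res["min_eigenvector_cosine"] > 1 - 1e-8

    def test_generalized_eigen_residual(self):
        from careact.validation import eigensolver_agreement

        res = eigensolver_agreement(seed=7)
        assert res["max_generalized_residual"] <= 1e-6

    def test_subspace_dimension_bound(self, rng):
        X, y = make_gaussian_patterns(n_classes=4, n_features=30, n_per_class=10, seed=2)
        model = fit_mda(X, y, lam=0.5)
        assert model.n_components <= 3

    def test_label_permutation_preserves_span(self):
        X, y = make_gaussian_patterns(n_classes=3, n_features=10, n_per_class=8, seed=4)
        m1 = fit_mda(X, y, lam=0.3)
        perm = np.random.default_rng(0).permutation(len(y))
        m2 = fit_mda(X[perm], y[perm], lam=0.3)
        # identical spans: projection matrices onto the subspaces agree
        P1 = m1.W @ np.linalg.pinv(m1.W)
        P2 = m2.W @ np.linalg.pinv(m2.W)
        assert np.allclose(P1, P2, atol=1e-8)

    def test_nonfinite_rejected(self):
        X, y = make_gaussian_patterns(n_classes=3, n_features=5, n_per_class=4, seed=1)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_mda(X, y)


class TestClassify:
    @pytest.fixture(scope="class")
    def model(self):
        X, y = make_gaussian_patterns(n_classes=4, n_features=20, n_per_class=15,
                                      separation=8.0, seed=11)
        return fit_mda(X, y, lam=0.5), X, y

    def test_class_mean_classified_to_class(self, model):
        m, X, y = model
        for c in m.classes:
            mean_x = X[y == c].mean(axis=0)
            pred, _ = classify(m, mean_x)
            assert pred[0] == c

    def test_rest_mean_distance_zero(self, model):
        m, X, y = model
        rest_mean = X[y == "rest"].mean(axis=0)
        _, dist = classify(m, rest_mean)
        assert dist[0] == pytest.approx(0.0, abs=1e-6)

    def test_high_separation_heldout_perfect(self):
        X, y = make_gaussian_patterns(n_classes=5, n_features=40, n_per_class=20,
                                      separation=6.0, seed=12, equal_norm=True)
        acc = cross_validate(X, y, lam=0.5, n_rep=100, seed=13)
        assert acc.mean() >= 0.95

    def test_dimension_mismatch_rejected(self, model):
        m, _X, _y = model
        with pytest.raises(ValueError):
            classify(m, np.zeros(7))


class TestCrossValidation:
    def test_duplicated_noiseless_data_perfect(self):
        base = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0], [0, 5], [0, 5]])
        X = np.tile(base, (10, 1))
        y = np.tile(["rest", "rest", "a", "a", "b", "b"], 10)
        acc = cross_validate(X, y, lam=0.5, n_rep=20, seed=1)
        assert acc.mean() == 1.0

    def test_shuffled_labels_at_chance(self, rng):
        # separation 0 and permuted labels: held-out accuracy must sit at
        # 1/N. Averaged over independent datasets because CV on a single
        # fixed noise realization has large dataset-level variance.
        means = []
        for s in range(10):
            X, y = make_gaussian_patterns(n_classes=4, n_features=12, n_per_class=25,
                                          separation=0.0, seed=30 + s)
            ys = rng.permutation(y)
            means.append(cross_validate(X, ys, lam=0.5, n_rep=20, seed=s).mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.25) < 3 * max(se, 0.02)

    def test_accuracy_increases_with_separation(self):
        means = []
        for sep, seed in ((1.0, 5), (3.0, 6), (6.0, 7)):
            X, y = make_gaussian_patterns(n_classes=4, n_features=15, n_per_class=12,
                                          separation=sep, seed=seed)
            means.append(cross_validate(X, y, lam=0.5, n_rep=60, seed=8).mean())
        assert means[0] < means[1] <= means[2] + 0.02

    def test_singleton_class_rejected(self):
        X = np.zeros((5, 2))
        y = ["a", "a", "b", "b", "c"]
        with pytest.raises(ValueError):
            cross_validate(X, y, n_rep=2)


class TestLambdaSelection:
    def test_single_point_grid(self):
        X, y = make_gaussian_patterns(n_classes=3, n_features=8, n_per_class=10, seed=9)
        assert select_lambda(X, y, grid=(0.5,), n_rep=5) == 0.5

    def test_well_conditioned_prefers_small_lambda(self):
        X, y = make_gaussian_patterns(n_classes=3, n_features=6, n_per_class=40,
                                      separation=6.0, seed=10)
        lam = select_lambda(X, y, grid=(0.05, 0.3, 0.7), n_rep=20, seed=11)
        assert lam == 0.05  # accuracy saturated; tie resolves to smallest

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(np.zeros((4, 2)), ["a", "a", "b", "b"], grid=())
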