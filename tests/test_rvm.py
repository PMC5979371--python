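"""RVM design matrix, posterior oracles, regression/classification behavior."""

import numpy as np
import pytest
from scipy.special import expit

import ppirvm as pv
from ppirvm import rvm as rvm_mod


def dense_posterior_oracle(Phi, alpha, sigma2, t):
    """Independent dense-algebra evaluation of the weight posterior."""
    A = np.diag(alpha)
    Sigma = np.linalg.inv(Phi.T @ Phi / sigma2 + A)
    mu = Sigma @ Phi.T @ t / sigma2
    return Sigma, mu


def irls_oracle(Phi, y, alpha, max_iter=200):
    """Independent Newton iteration to the penalized Bernoulli mode."""
    w = np.zeros(Phi.shape[1])
    for _ in range(max_iter):
        p = expit(Phi @ w)
        g = Phi.T @ (y - p) - alpha * w
        B = np.clip(p * (1 - p), 1e-12, None)
        H = Phi.T @ np.diag(B) @ Phi + np.diag(alpha)
        step = np.linalg.solve(H, g)
        w = w + step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = expit(Phi @ w)
    B = np.clip(p * (1 - p), 1e-12, None)
    Sigma = np.linalg.inv(Phi.T @ np.diag(B) @ Phi + np.diag(alpha))
    return w, Sigma


class TestDesignMatrix:
    def test_kernel_diagonal_is_one_on_training_points(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 3))
        dm = pv.design_matrix(X, X, pv.KernelSpec(gamma=0.7))
        K = dm.values[:, 1:]
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_array_equal(dm.values[:, 0], 1.0)

    def test_entries_match_scalar_evaluation(self):
        X = np.array([[0.0, 1.0], [2.0, -1.0]])
        basis = np.array([[1.0, 1.0], [0.5, 0.0]])
        gamma = 0.3
        dm = pv.design_matrix(X, basis, pv.KernelSpec(gamma=gamma))
        for i in range(2):
            for j in range(2):
                expected = np.exp(-gamma * np.sum((X[i] - basis[j]) ** 2))
                assert dm.values[i, j + 1] == pytest.approx(expected, rel=1e-12)

    def test_large_gamma_limit_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 2))
        dm = pv.design_matrix(X, X, pv.KernelSpec(gamma=1e8, include_bias=False))
        np.testing.assert_allclose(dm.values, np.eye(5), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pv.design_matrix(np.zeros((3, 2)), np.zeros((3, 4)), pv.KernelSpec(gamma=1.0))

    def test_nonfinite_rejected(self):
        X = np.zeros((3, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            pv.design_matrix(X, np.zeros((3, 2)), pv.KernelSpec(gamma=1.0))


class TestRegressionPosterior:
    def test_matches_dense_oracle_on_fixed_hyperparameters(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 2))
        t = rng.standard_normal(5)
        Phi = pv.design_matrix(X, X, pv.KernelSpec(gamma=0.5)).values
        alpha = np.abs(rng.standard_normal(6)) + 0.1
        sigma2 = 0.3
        Sigma, mu = pv.regression_posterior(Phi, alpha, sigma2, t)
        Sigma_o, mu_o = dense_posterior_oracle(Phi, alpha, sigma2, t)
        np.testing.assert_allclose(Sigma, Sigma_o, atol=1e-10)
        np.testing.assert_allclose(mu, mu_o, atol=1e-10)

    def test_log_marginal_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        Phi = rng.standard_normal((6, 4))
        alpha = np.abs(rng.standard_normal(4)) + 0.5
        t = rng.standard_normal(6)
        sigma2 = 0.7
        got = pv.regression_log_marginal(Phi, alpha, sigma2, t)
        Omega = sigma2 * np.eye(6) + Phi @ np.diag(1 / alpha) @ Phi.T
        want = -0.5 * (6 * np.log(2 * np.pi) + np.linalg.slogdet(Omega)[1]
                       + t @ np.linalg.solve(Omega, t))
        assert got == pytest.approx(want, abs=1e-10)


class TestRegressorFit:
    def test_noiseless_realizable_target_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 1))
        kernel = pv.KernelSpec(gamma=1.0)
        Phi = pv.design_matrix(X, X, kernel).values
        w_true = np.zeros(31)
        w_true[[0, 5, 12]] = [1.0, -2.0, 3.0]
        t = Phi @ w_true
        model, diag = pv.fit_rvm_regressor(X, t, kernel=kernel)
        np.testing.assert_allclose(pv.predict(model, X), t, atol=1e-6)
        assert model.noise_variance < 1e-6

    def test_gammas_within_unit_interval(self):
        rng = np.random.default_rng(5)
        X = np.linspace(-4, 4, 40)[:, None]
        t = np.sinc(X.ravel()) + 0.1 * rng.standard_normal(40)
        _, diag = pv.fit_rvm_regressor(X, t, kernel=pv.KernelSpec(gamma=0.5))
        assert np.all(diag.gammas >= -1e-10)
        assert np.all(diag.gammas <= 1 + 1e-10)

    def test_marginal_likelihood_nondecreasing_with_noise(self):
        rng = np.random.default_rng(6)
        X = np.linspace(-5, 5, 50)[:, None]
        t = np.sinc(X.ravel()) + 0.05 * rng.standard_normal(50)
        _, diag = pv.fit_rvm_regressor(X, t, kernel=pv.KernelSpec(gamma=0.5))
        trace = np.array(diag.log_marginal_trace)
        assert trace.size >= 2
        assert np.min(np.diff(trace)) > -1e-6

    def test_constant_targets_fit_without_error(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 2))
        model, _ = pv.fit_rvm_regressor(X, np.full(10, 3.0))
        np.testing.assert_allclose(pv.predict(model, X), 3.0, atol=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pv.fit_rvm_regressor(np.zeros((1, 2)), np.zeros(1))


def make_blobs(n_per_class=40, d=2, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-sep / 2, 0.5, (n_per_class, d)),
        rng.normal(sep / 2, 0.5, (n_per_class, d)),
    ])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestClassifierFit:
    def test_separable_blobs_perfect_and_sparse(self):
        X, y = make_blobs(40)
        model, _ = pv.fit_rvm_classifier(X, y)
        scores = pv.predict(model, X)
        assert np.mean((scores >= 0.5) == y) == 1.0
        assert model.n_relevance_vectors <= 0.2 * len(y)

    def test_label_flip_complements_probabilities(self):
        X, y = make_blobs(20, seed=1)
        rng = np.random.default_rng(2)
        X_test = rng.standard_normal((30, 2))
        m1, _ = pv.fit_rvm_classifier(X, y)
        m2, _ = pv.fit_rvm_classifier(X, 1 - y)
        np.testing.assert_allclose(
            pv.predict(m1, X_test), 1 - pv.predict(m2, X_test), atol=1e-6
        )

    def test_inner_laplace_step_matches_irls_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 2))
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        Phi = pv.design_matrix(X, X, pv.KernelSpec(gamma=0.8)).values
        alpha = np.full(7, 1e-2)
        w, Sigma, _ = rvm_mod._irls_mode(Phi, y, alpha, np.zeros(7))
        w_o, Sigma_o = irls_oracle(Phi, y, alpha)
        np.testing.assert_allclose(w, w_o, atol=1e-8)
        np.testing.assert_allclose(Sigma, Sigma_o, atol=1e-8)

    def test_scores_strictly_inside_unit_interval(self, small_null_dataset):
        X = np.vstack([p.values for p in small_null_dataset])
        y = np.array([p.label for p in small_null_dataset])
        model, _ = pv.fit_rvm_classifier(X, y, max_iter=50)
        s = pv.predict(model, X)
        assert np.all((s > 0) & (s < 1))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        with pytest.raises(ValueError, match="single class"):
            pv.fit_rvm_classifier(X, np.ones(6))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            pv.fit_rvm_classifier(np.zeros((3, 2)), np.array([0, 1, 0]))


class TestModelProperties:
    def test_pruned_basis_functions_do_not_affect_predictions(self):
        X, y = make_blobs(30, seed=4)
        model, _ = pv.fit_rvm_classifier(X, y)
        rng = np.random.default_rng(5)
        X_test = rng.standard_normal((20, 2))
        got = pv.predict(model, X_test)
        # dense recomputation over the FULL training basis, pruned weights = 0
        full_w = np.zeros(len(y) + 1)
        kept_cols = [0] if model.has_bias else []
        K_train = pv.design_matrix(X, X, model.kernel).values
        # locate each relevance vector's column in the full design
        for rv, w in zip(model.relevance_vectors,
                         model.weights_mean[1 if model.has_bias else 0:]):
            idx = int(np.argmin(np.linalg.norm(X - rv, axis=1))) + 1
            full_w[idx] = w
        if model.has_bias:
            full_w[0] = model.weights_mean[0]
        Phi_test = pv.design_matrix(X_test, X, model.kernel).values
        dense = expit(Phi_test @ full_w)
        np.testing.assert_allclose(got, dense, atol=1e-10)

    def test_sparsity_on_larger_problem(self):
        X, y = make_blobs(100, sep=2.0, seed=6)
        model, _ = pv.fit_rvm_classifier(X, y)
        assert model.n_relevance_vectors < len(y) / 2

    def test_fit_is_deterministic(self):
        X, y = make_blobs(25, seed=7)
        m1, d1 = pv.fit_rvm_classifier(X, y)
        m2, d2 = pv.fit_rvm_classifier(X, y)
        assert np.array_equal(m1.weights_mean, m2.weights_mean)
        assert np.array_equal(m1.alphas, m2.alphas)
        assert d1.iterations_run == d2.iterations_run

    def test_permutation_equivariance(self):
        X, y = make_blobs(20, seed=8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(y))
        m1, _ = pv.fit_rvm_classifier(X, y)
        m2, _ = pv.fit_rvm_classifier(X[perm], y[perm])
        X_test = rng.standard_normal((15, 2))
        np.testing.assert_allclose(pv.predict(m1, X_test), pv.predict(m2, X_test),
                                   atol=1e-10)

    def test_prediction_dimension_mismatch_rejected(self):
        X, y = make_blobs(10, seed=10)
        model, _ = pv.fit_rvm_classifier(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            pv.predict(model, np.zeros((4, 3)))
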