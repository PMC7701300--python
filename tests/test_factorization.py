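import numpy as np
import pytest

from mfmda import factorization as fz


def _random_instance(rng, n_m=6, n_d=4, k=2, density=0.4):
    Y = (rng.random((n_m, n_d)) < density).astype(float)
    S_m = rng.random((n_m, n_m))
    S_m = (S_m + S_m.T) / 2
    np.fill_diagonal(S_m, 1.0)
    S_d = rng.random((n_d, n_d))
    S_d = (S_d + S_d.T) / 2
    np.fill_diagonal(S_d, 1.0)
    return Y, S_m, S_d


class TestLaplacian:
    def test_identity_similarity_gives_zero_laplacian(self):
        gl = fz.laplacian(np.eye(2))
        np.testing.assert_array_equal(gl.L, np.zeros((2, 2)))

    def test_complete_graph_with_self_loops(self):
        gl = fz.laplacian(np.ones((2, 2)))
        np.testing.assert_array_equal(gl.L, [[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_array_equal(gl.D_diag, [2.0, 2.0])

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(2)
        S = rng.random((7, 7))
        S = (S + S.T) / 2
        gl = fz.laplacian(S)
        np.testing.assert_allclose(gl.L.sum(axis=1), 0.0, atol=1e-10)

    def test_quadratic_form_identity(self):
        # x^T L x = 1/2 sum_ij S_ij (x_i - x_j)^2
        rng = np.random.default_rng(3)
        for _ in range(20):
            S = rng.random((5, 5))
            S = (S + S.T) / 2
            x = rng.standard_normal(5)
            lhs = x @ fz.laplacian(S).L @ x
            rhs = 0.5 * sum(
                S[i, j] * (x[i] - x[j]) ** 2
                for i in range(5) for j in range(5))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_asymmetric_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            fz.laplacian(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestObjective:
    def test_zero_factors_count_known_associations(self):
        Y = np.array([[1.0, 0.0], [1.0, 1.0]])
        hyper = fz.Hyperparams(k=2, lambda_l=0, lambda_m=0, lambda_d=0)
        val = fz.objective(Y, None, np.zeros((2, 2)), np.zeros((2, 2)),
                           np.eye(2), np.eye(2), hyper)
        assert val == 3.0

    def test_exact_factorization_scores_zero(self, toy):
        hyper = toy["stationary_hyper"]
        val = fz.objective(toy["stationary_Y"], None, toy["stationary_W"],
                           toy["stationary_H"], np.eye(3), np.eye(2), hyper)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_trace_form_equals_unordered_pairwise_sum(self):
        # dual-formula oracle: the graph penalty as coded (trace form) must
        # equal the brute-force sum over unordered entity pairs
        rng = np.random.default_rng(4)
        Y, S_m, S_d = _random_instance(rng)
        W, H = rng.random((6, 2)), rng.random((4, 2))
        hyper = fz.Hyperparams(k=2, lambda_l=0.0, lambda_m=0.7, lambda_d=0.3)
        val = fz.objective(Y, None, W, H, S_m, S_d, hyper)
        fit_term = ((Y - W @ H.T) ** 2).sum()
        graph_m = sum(((W[i] - W[p]) ** 2).sum() * S_m[i, p]
                      for i in range(6) for p in range(i + 1, 6))
        graph_d = sum(((H[j] - H[q]) ** 2).sum() * S_d[j, q]
                      for j in range(4) for q in range(j + 1, 4))
        expected = fit_term + 0.7 * graph_m + 0.3 * graph_d
        assert val == pytest.approx(expected, rel=1e-9)

    def test_negative_factors_rejected(self):
        hyper = fz.Hyperparams(k=1)
        with pytest.raises(ValueError, match="nonnegative"):
            fz.objective(np.ones((2, 2)), None, -np.ones((2, 1)),
                         np.ones((2, 1)), np.eye(2), np.eye(2), hyper)


def _plain_nmf_step(Y, W, H, eps):
    """Independently coded multiplicative NMF update (W first, then H)."""
    W2 = W * (Y @ H) / (W @ (H.T @ H) + eps)
    H2 = H * (Y.T @ W2) / (H @ (W2.T @ W2) + eps)
    return W2, H2


class TestUpdateStep:
    def test_fixed_point_at_stationary_factors(self, toy):
        W, H = toy["stationary_W"], toy["stationary_H"]
        W2, H2 = fz.update_step(toy["stationary_Y"], W, H, np.eye(3),
                                np.eye(2), np.ones(3), np.ones(2),
                                toy["stationary_hyper"])
        np.testing.assert_allclose(W2, W, atol=1e-12)
        np.testing.assert_allclose(H2, H, atol=1e-12)

    def test_reduces_to_plain_nmf_without_regularization(self):
        rng = np.random.default_rng(6)
        Y = (rng.random((6, 4)) < 0.5).astype(float)
        hyper = fz.Hyperparams(k=3, lambda_l=0.0, lambda_m=0.0, lambda_d=0.0)
        W = rng.random((6, 3)) + 0.1
        H = rng.random((4, 3)) + 0.1
        Wr, Hr = W.copy(), H.copy()
        S_m, S_d = np.eye(6), np.eye(4)
        for _ in range(10):
            W, H = fz.update_step(Y, W, H, S_m, S_d, np.ones(6), np.ones(4),
                                  hyper)
            Wr, Hr = _plain_nmf_step(Y, Wr, Hr, hyper.eps)
            np.testing.assert_allclose(W, Wr, atol=1e-12)
            np.testing.assert_allclose(H, Hr, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.2, 1.0])
    def test_single_step_never_increases_objective(self, lam):
        rng = np.random.default_rng(7)
        hyper = fz.Hyperparams(k=2, lambda_l=lam, lambda_m=lam, lambda_d=lam)
        for _ in range(30):
            Y, S_m, S_d = _random_instance(rng)
            W = rng.random((6, 2)) + 0.05
            H = rng.random((4, 2)) + 0.05
            before = fz.objective(Y, None, W, H, S_m, S_d, hyper)
            W2, H2 = fz.update_step(
                Y, W, H, S_m, S_d, S_m.sum(1), S_d.sum(1), hyper)
            after = fz.objective(Y, None, W2, H2, S_m, S_d, hyper)
            assert after <= before + 1e-9 * abs(before)
            assert W2.min() >= 0 and H2.min() >= 0

    def test_accepts_diagonal_degree_matrices(self, toy):
        W, H = toy["stationary_W"], toy["stationary_H"]
        W2, _ = fz.update_step(toy["stationary_Y"], W, H, np.eye(3),
                               np.eye(2), np.eye(3), np.eye(2),
                               toy["stationary_hyper"])
        np.testing.assert_allclose(W2, W, atol=1e-12)


class TestFit:
    def test_recovers_planted_low_rank_structure(self):
        # exactly rank-3 binary matrix: block structure over 3 groups
        rng = np.random.default_rng(8)
        row_g = rng.integers(0, 3, size=30)
        col_g = rng.integers(0, 3, size=20)
        Y = (row_g[:, None] == col_g[None, :]).astype(float)
        hyper = fz.Hyperparams(k=3, lambda_l=0.0, lambda_m=0.0, lambda_d=0.0,
                               max_iter=2000, tol=1e-10, seed=0)
        model = fz.fit(Y, np.eye(30), np.eye(20), hyper)
        resid = ((Y - fz.predict(model)) ** 2).sum()
        assert resid < 0.05 * (Y**2).sum()

    def test_infinite_tolerance_stops_after_one_iteration(self):
        hyper = fz.Hyperparams(k=2, tol=np.inf)
        model = fz.fit(np.eye(3), np.eye(3), np.eye(3), hyper)
        assert model.iterations_run == 1
        assert len(model.objective_trace) == 2
        assert model.converged

    def test_same_seed_is_bitwise_identical(self):
        rng = np.random.default_rng(9)
        Y, S_m, S_d = _random_instance(rng, 8, 5, 2)
        hyper = fz.Hyperparams(k=3, max_iter=40, seed=123)
        a = fz.fit(Y, S_m, S_d, hyper)
        b = fz.fit(Y, S_m, S_d, hyper)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)
        assert a.objective_trace == b.objective_trace

    def test_trace_is_monotone_and_factors_nonnegative(self):
        rng = np.random.default_rng(10)
        Y, S_m, S_d = _random_instance(rng, 10, 8, 3)
        hyper = fz.Hyperparams(k=4, max_iter=100, tol=1e-12)
        model = fz.fit(Y, S_m, S_d, hyper)
        t = np.array(model.objective_trace)
        assert (t[1:] <= t[:-1] + 1e-9 * np.abs(t[:-1])).all()
        assert model.W.min() >= 0 and model.H.min() >= 0

    def test_stronger_ridge_shrinks_factor_norms(self):
        rng = np.random.default_rng(11)
        diffs = []
        for seed in range(7):
            Y, S_m, S_d = _random_instance(rng, 10, 8, 3)
            base = fz.Hyperparams(k=3, max_iter=300, tol=1e-10, seed=seed)
            small = fz.fit(Y, S_m, S_d, base.replace(lambda_l=0.5))
            big = fz.fit(Y, S_m, S_d, base.replace(lambda_l=1.0))
            norm = lambda m: np.linalg.norm(m.W) + np.linalg.norm(m.H)
            diffs.append(norm(small) - norm(big))
        assert np.median(diffs) > 0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            fz.fit(np.eye(3), np.eye(2), np.eye(3), fz.Hyperparams(k=1))


class TestPredict:
    def test_zero_factors_give_zero_scores(self):
        model = fz.FactorModel(np.zeros((2, 1)), np.zeros((3, 1)), [0.0],
                               True, 0, fz.Hyperparams(k=1))
        np.testing.assert_array_equal(fz.predict(model), np.zeros((2, 3)))

    def test_rank_one_product(self):
        model = fz.FactorModel(np.array([[2.0]]), np.array([[3.0]]), [0.0],
                               True, 0, fz.Hyperparams(k=1))
        assert fz.predict(model)[0, 0] == 6.0

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(12)
        W, H = rng.random((5, 3)), rng.random((4, 3))
        model = fz.FactorModel(W, H, [0.0], True, 0, fz.Hyperparams(k=3))
        expected = np.array([[W[i] @ H[j] for j in range(4)]
                             for i in range(5)])
        np.testing.assert_allclose(fz.predict(model), expected, atol=1e-12)
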