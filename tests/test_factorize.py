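"""Solver contracts: orthogonal baselines, constrained NMF, objectives."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import hsunmix as h
from hsunmix.factorize import (
    WORKED_PIXEL_ABUNDANCE,
    count_insignificant,
    objective,
    reconstruct,
    residual,
)
from hsunmix.graph import SpatialGraph, build_grid_adjacency, edge_roughness


class TestSVD:
    def test_diagonal_case(self):
        model = h.svd_truncated(np.diag([3.0, 1.0]), 1)
        np.testing.assert_allclose(model.singular_values, [3.0])
        np.testing.assert_allclose(reconstruct(model), [[3.0, 0.0], [0.0, 0.0]], atol=1e-12)

    def test_full_rank_reconstruction_exact(self, rng):
        X = rng.normal(size=(5, 4))
        model = h.svd_truncated(X, 4)
        assert np.linalg.norm(X - reconstruct(model)) < 1e-10

    def test_error_matches_eckart_young_oracle(self, rng):
        """Truncation error equals the tail eigenvalue sum of X^T X."""
        X = rng.normal(size=(6, 5))
        k = 2
        model = h.svd_truncated(X, k)
        err = np.sum((X - reconstruct(model)) ** 2)
        eigs = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        assert err == pytest.approx(np.sum(eigs[k:]), rel=1e-10)

    def test_orthonormal_factors(self, rng):
        model = h.svd_truncated(rng.normal(size=(8, 7)), 3)
        np.testing.assert_allclose(model.U.T @ model.U, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(model.V @ model.V.T, np.eye(3), atol=1e-8)
        assert np.all(np.diff(model.singular_values) <= 0)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            h.svd_truncated(rng.normal(size=(3, 3)), 4)


class TestPCA:
    def test_identical_columns_have_zero_variance(self):
        A = np.tile(np.arange(5.0)[:, None], (1, 6))
        model = h.pca(A, 2)
        np.testing.assert_allclose(model.singular_values, 0.0, atol=1e-10)

    def test_diagonal_point_cloud_first_component(self, rng):
        t = rng.normal(size=200)
        A = np.vstack([t, t]) + rng.normal(scale=1e-3, size=(2, 200))
        model = h.pca(A, 1)
        np.testing.assert_allclose(np.abs(model.U[:, 0]), [np.sqrt(0.5)] * 2, atol=1e-2)

    def test_matches_covariance_eigen_oracle(self, rng):
        """PCA components equal the eigenvectors of the sample covariance."""
        A = rng.normal(size=(6, 40))
        k = 3
        model = h.pca(A, k)
        Xc = A - A.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        for i in range(k):
            v = eigvec[:, order[i]]
            cos = abs(v @ model.U[:, i])
            assert cos == pytest.approx(1.0, abs=1e-8)
            assert model.singular_values[i] ** 2 == pytest.approx(eigval[order[i]], rel=1e-8)

    def test_equals_svd_of_centered_data(self, rng):
        A = rng.uniform(size=(7, 9))
        Xc = A - A.mean(axis=1, keepdims=True)
        m1 = h.pca(A, 3)
        m2 = h.svd_truncated(Xc, 3)
        np.testing.assert_allclose(m1.U, m2.U, atol=1e-8)
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-8)

    def test_full_rank_reconstruct_recovers_data(self, rng):
        A = rng.uniform(size=(5, 8))
        model = h.pca(A, 5)
        np.testing.assert_allclose(reconstruct(model), A, atol=1e-8)

    def test_explained_variance_sums_to_one_at_full_rank(self, rng):
        model = h.pca(rng.uniform(size=(4, 10)), 4)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)


class TestNMFBasics:
    def test_rank_one_data_fit_exactly(self, rng):
        u = rng.uniform(0.5, 1.5, size=12)
        v = rng.uniform(0.5, 1.5, size=15)
        X = np.outer(u, v)
        model = h.nmf(X, h.UnmixingConfig(k=1, seed=0, tol=1e-14, max_iter=2000))
        rel = np.linalg.norm(X - model.U @ model.V) / np.linalg.norm(X)
        assert rel <= 1e-6

    def test_zero_matrix_gives_zero_objective(self):
        X = np.zeros((4, 6))
        model = h.nmf(X, h.UnmixingConfig(k=2, seed=0, max_iter=20))
        assert objective(X, model.U, model.V, model.config) == pytest.approx(0.0, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            h.nmf(np.array([[1.0, -1.0]]), h.UnmixingConfig(k=1))

    def test_large_k_warns(self, rng):
        with pytest.warns(RuntimeWarning, match="low-rank"):
            h.nmf(rng.uniform(size=(3, 4)), h.UnmixingConfig(k=3, max_iter=5))

    def test_factors_non_negative(self, default_model):
        assert default_model.U.min() >= 0
        assert default_model.V.min() >= 0

    def test_bit_reproducible_for_fixed_seed(self, rng):
        X = rng.uniform(size=(10, 20))
        cfg = h.UnmixingConfig(k=3, seed=7, max_iter=50)
        m1 = h.nmf(X, cfg)
        m2 = h.nmf(X, cfg)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)
        np.testing.assert_array_equal(m1.objective_trace, m2.objective_trace)

    def test_objective_agrees_with_sklearn_nmf(self, rng):
        """Independent route: sklearn's NMF reaches a comparable optimum."""
        from sklearn.decomposition import NMF

        X = rng.uniform(size=(20, 30))
        mine = h.nmf(X, h.UnmixingConfig(k=3, seed=0, solver="hals", init="nndsvd",
                                         tol=1e-10, max_iter=2000))
        ref = NMF(n_components=3, init="nndsvda", solver="cd", tol=1e-10,
                  max_iter=2000, random_state=0).fit(X)
        err_mine = np.linalg.norm(X - mine.U @ mine.V)
        err_ref = np.sqrt(ref.reconstruction_err_**2)
        assert err_mine == pytest.approx(err_ref, rel=0.02)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"lambda1": 0.1},
            {"loss": "kl"},
            {"solver": "hals", "lambda1": 0.05},
            {"lambda1": 0.05, "lambda2": 0.5, "_graph": True},
        ],
        ids=["plain", "sparse", "kl", "hals", "graph"],
    )
    def test_objective_trace_non_increasing(self, seed, kwargs, rng):
        kwargs = dict(kwargs)
        use_graph = kwargs.pop("_graph", False)
        X = np.random.default_rng(seed).uniform(size=(15, 24))
        graph = build_grid_adjacency((4, 6)) if use_graph else None
        cfg = h.UnmixingConfig(k=3, seed=seed, max_iter=120, **kwargs)
        model = h.nmf(X, cfg, graph=graph)
        tr = model.objective_trace
        assert np.all(np.diff(tr) <= 1e-10 * np.maximum(np.abs(tr[:-1]), 1.0))
        assert model.meta["monotone"]


class TestSparseNMF:
    def test_lambda_zero_identical_trajectory(self, rng):
        X = rng.uniform(size=(12, 18))
        cfg0 = h.UnmixingConfig(k=3, seed=1, max_iter=60)
        cfg1 = h.UnmixingConfig(k=3, seed=1, lambda1=0.0, max_iter=60)
        m0 = h.nmf(X, cfg0)
        m1 = h.sparse_nmf(X, cfg1)
        np.testing.assert_array_equal(m0.U, m1.U)
        np.testing.assert_array_equal(m0.objective_trace, m1.objective_trace)

    def test_small_entry_count_non_decreasing_in_lambda(self, default_dm):
        counts = []
        for lam in (0.0, 0.01, 0.1, 1.0):
            cfg = h.UnmixingConfig(k=3, seed=0, lambda1=lam, max_iter=300)
            model = h.sparse_nmf(default_dm, cfg)
            counts.append(int(np.count_nonzero(model.V < 1e-3)))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            h.UnmixingConfig(k=2, lambda1=-1.0).validate()

    def test_worked_pixel_significance_floor(self):
        """Two of four abundances in the textbook pixel sit below 0.05."""
        assert WORKED_PIXEL_ABUNDANCE[2] == 0.015
        assert count_insignificant(WORKED_PIXEL_ABUNDANCE, floor=0.05) == 2


class TestGraphNMF:
    def test_lambda2_zero_identical_to_sparse(self, rng):
        X = rng.uniform(size=(10, 12))
        g = build_grid_adjacency((3, 4))
        cfg = h.UnmixingConfig(k=2, seed=2, lambda1=0.05, max_iter=60)
        m0 = h.sparse_nmf(X, cfg)
        m1 = h.nmf(X, h.UnmixingConfig(k=2, seed=2, lambda1=0.05, lambda2=0.0, max_iter=60), graph=g)
        np.testing.assert_array_equal(m0.U, m1.U)
        np.testing.assert_array_equal(m0.V, m1.V)

    def test_identical_pixels_forced_equal(self):
        """Two identical spectra on a connected pair recover equal abundances."""
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        g = SpatialGraph(W=W)
        X = np.array([[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]])
        cfg = h.UnmixingConfig(k=2, seed=3, lambda2=1.0, max_iter=2000, tol=1e-12)
        model = h.nmf(X, cfg, graph=g)
        np.testing.assert_allclose(model.V[:, 0], model.V[:, 1], atol=1e-6)

    def test_smoothing_reduces_edge_roughness(self, rng):
        """The contrast between runs without and with the spatial penalty."""
        V = h.make_abundances((16, 16), 3, smoothness_scale=3, sparsity=0.0, seed=1)
        idx = rng.choice(256, 40, replace=False)
        V[:, idx] = rng.permutation(V[:, idx].T).T  # salt-and-pepper corruption
        U = h.make_endmembers(3, 80, seed=2)
        X = np.clip(U @ V + rng.normal(scale=0.01, size=(80, 256)), 0, None)
        g = build_grid_adjacency((16, 16))
        m0 = h.nmf(X, h.UnmixingConfig(k=3, seed=0, lambda1=0.01, max_iter=300), graph=g)
        m1 = h.nmf(X, h.UnmixingConfig(k=3, seed=0, lambda1=0.01, lambda2=0.1, max_iter=300), graph=g)
        assert edge_roughness(m1.V, g) < edge_roughness(m0.V, g)

    def test_graph_size_mismatch_rejected(self, rng):
        g = build_grid_adjacency((2, 2))
        with pytest.raises(ValueError):
            h.nmf(rng.uniform(size=(3, 6)), h.UnmixingConfig(k=2, lambda2=0.1), graph=g)

    def test_literal_penalty_form_runs_and_is_reported(self, rng):
        X = rng.uniform(size=(8, 12))
        g = build_grid_adjacency((3, 4))
        cfg = h.UnmixingConfig(k=2, seed=0, lambda2=0.01, max_iter=40, literal_penalty=True)
        model = h.nmf(X, cfg, graph=g)
        assert model.config.literal_penalty
        assert np.isfinite(model.objective_trace).all()


class TestSumToOne:
    def test_single_component_is_all_ones(self, rng):
        X = rng.uniform(0.1, 1.0, size=(6, 9))
        model = h.sum_to_one_nmf(X, h.UnmixingConfig(k=1, loss="kl", sum_to_one=True, max_iter=50))
        np.testing.assert_allclose(model.V, 1.0, atol=1e-9)

    def test_columns_on_simplex(self, rng):
        X = rng.uniform(0.0, 2.0, size=(10, 30))
        model = h.sum_to_one_nmf(X, h.UnmixingConfig(k=3, loss="kl", sum_to_one=True, seed=0))
        assert np.abs(model.V.sum(axis=0) - 1.0).max() <= 1e-9
        assert model.V.min() >= 0

    def test_zero_pixel_column_gets_uniform_abundance(self, rng):
        X = rng.uniform(0.1, 1.0, size=(5, 8))
        X[:, 3] = 0.0
        with pytest.warns(RuntimeWarning, match="all-zero pixel"):
            model = h.sum_to_one_nmf(X, h.UnmixingConfig(k=4, loss="kl", sum_to_one=True, max_iter=30))
        np.testing.assert_allclose(model.V[:, 3], 0.25, atol=1e-9)

    def test_recovers_simplex_ground_truth(self):
        gt = h.default_ground_truth(seed=0, sum_to_one=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = h.cube_to_matrix(h.make_cube(gt))
        model = h.sum_to_one_nmf(dm, h.UnmixingConfig(k=3, loss="kl", sum_to_one=True,
                                                      seed=0, max_iter=500))
        rep = h.recovery_report(model, gt)
        assert np.abs(model.V.sum(axis=0) - 1.0).max() <= 1e-9
        assert rep.abundance_rmse <= 0.05

    def test_frobenius_sum_to_one_rejected(self):
        with pytest.raises(ValueError, match="pLSI"):
            h.UnmixingConfig(k=2, loss="frobenius", sum_to_one=True).validate()


class TestObjective:
    def test_exact_factorization_zero(self, rng):
        U = rng.uniform(size=(5, 2))
        V = rng.uniform(size=(2, 7))
        X = U @ V
        assert objective(X, U, V, h.UnmixingConfig(k=2)) == pytest.approx(0.0, abs=1e-20)

    def test_zero_data_gives_squared_frobenius_norm(self, rng):
        U = rng.uniform(size=(4, 2))
        V = rng.uniform(size=(2, 6))
        f = np.linalg.norm(U @ V)
        assert objective(np.zeros((4, 6)), U, V, h.UnmixingConfig(k=2)) == pytest.approx(f**2)

    def test_matches_elementwise_loop_oracle(self, rng):
        X = rng.uniform(0.1, 1.0, size=(4, 5))
        U = rng.uniform(0.1, 1.0, size=(4, 2))
        V = rng.uniform(0.1, 1.0, size=(2, 5))
        g = build_grid_adjacency((1, 5))
        cfg = h.UnmixingConfig(k=2, lambda1=0.3, lambda2=0.2)
        R = U @ V
        expected = sum((X[i, j] - R[i, j]) ** 2 for i in range(4) for j in range(5))
        expected += 0.3 * sum(abs(V[i, j]) for i in range(2) for j in range(5))
        W = g.W.toarray()
        expected += 0.2 * 0.5 * sum(
            W[a, b] * np.sum((V[:, a] - V[:, b]) ** 2) for a in range(5) for b in range(5)
        )
        assert objective(X, U, V, cfg, graph=g) == pytest.approx(expected, rel=1e-12)

    def test_generalized_kl_conventions(self):
        X = np.array([[0.0, 2.0]])
        R = np.array([[1.0, 1.0]])
        cfg = h.UnmixingConfig(k=1, loss="kl")
        # 0 log 0 = 0 contributes Q; second entry contributes 2 log 2 - 1
        expected = 1.0 + (2 * np.log(2.0) - 2.0 + 1.0)
        assert objective(X, np.array([[1.0]]), R, cfg) == pytest.approx(expected)

    def test_reconstruction_term_invariant_to_exit_normalization(self, rng):
        X = rng.uniform(size=(8, 10))
        model = h.nmf(X, h.UnmixingConfig(k=2, seed=0, max_iter=50))
        scales = rng.uniform(0.5, 2.0, size=2)
        U2 = model.U * scales[None, :]
        V2 = model.V / scales[:, None]
        cfg = h.UnmixingConfig(k=2)
        assert objective(X, U2, V2, cfg) == pytest.approx(
            objective(X, model.U, model.V, cfg), rel=1e-10
        )


class TestReconstructResidual:
    def test_exact_rank_data_residual_near_zero(self, rng):
        U = rng.uniform(0.2, 1.0, size=(20, 2))
        V = rng.uniform(0.2, 1.0, size=(2, 12))
        X = h.DataMatrix(U @ V, grid_shape=(3, 4))
        model = h.nmf(X, h.UnmixingConfig(k=2, seed=0, solver="hals", init="nndsvd",
                                          tol=1e-14, max_iter=4000))
        res = residual(model, X)
        assert res.shape == (3, 4)
        assert res.max() < 1e-6

    def test_residual_matches_columnwise_loop(self, default_model, default_dm):
        res = residual(default_model, default_dm).reshape(-1)
        R = reconstruct(default_model)
        for j in range(0, default_dm.n_pixels, 97):
            num = np.linalg.norm(default_dm.X[:, j] - R[:, j])
            den = np.linalg.norm(default_dm.X[:, j])
            assert res[j] == pytest.approx(num / den, rel=1e-10)
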