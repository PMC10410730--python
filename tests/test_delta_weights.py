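import numpy as np
import pytest

from dendrimod import delta_weights as dw


@pytest.fixture
def dx_random(rng):
    X = rng.normal(size=(25, 6))
    return dw.sample_differences(X, 60, seed=4)


class TestSampleDifferences:
    def test_two_rows_single_pair(self):
        X = np.array([[1.0, 2.0], [3.0, 5.0]])
        d = dw.sample_differences(X, 1, seed=0)
        i, j = d.pair_index[0]
        np.testing.assert_allclose(d.rows[0], X[i] - X[j])
        assert i != j

    def test_determinism(self, rng):
        X = rng.normal(size=(10, 3))
        a = dw.sample_differences(X, 20, seed=7)
        b = dw.sample_differences(X, 20, seed=7)
        np.testing.assert_array_equal(a.pair_index, b.pair_index)

    def test_rows_match_pairs_exactly(self, rng):
        X = rng.normal(size=(12, 4))
        d = dw.sample_differences(X, 30, seed=1)
        for r, (i, j) in enumerate(d.pair_index):
            np.testing.assert_array_equal(d.rows[r], X[i] - X[j])

    def test_duplicate_samples_allowed(self):
        X = np.ones((5, 3))
        d = dw.sample_differences(X, 8, seed=2)
        assert np.all(d.rows == 0.0)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            dw.sample_differences(np.ones((1, 3)), 1, seed=0)

    def test_without_replacement_when_available(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        d = dw.sample_differences(X, 30, seed=3)  # 45 pairs available
        codes = {tuple(sorted(p)) for p in map(tuple, d.pair_index)}
        assert len(codes) == 30

    def test_with_replacement_beyond_available(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        d = dw.sample_differences(X, 10, seed=3)  # only 3 pairs available
        assert len(d.rows) == 10


class TestDeltaPCA:
    def test_rank_one(self):
        rows = np.outer([1.0, -2.0, 3.0], [1.0, 0.0, 0.0, 0.0])
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((3, 2), int),
                                seed=0)
        wm = dw.delta_pca(d, 1)
        np.testing.assert_allclose(np.abs(wm.W[0]), [1, 0, 0, 0], atol=1e-12)

    def test_matches_svd_oracle(self, rng):
        rows = rng.normal(size=(20, 5))
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((20, 2), int),
                                seed=0)
        wm = dw.delta_pca(d, 3)
        _, _, Vt = np.linalg.svd(rows)
        for r in range(3):
            assert abs(wm.W[r] @ Vt[r]) > 1 - 1e-8

    def test_rows_orthonormal(self, dx_random):
        W = dw.delta_pca(dx_random, 4).W
        G = W @ W.T
        np.testing.assert_allclose(G, np.eye(4), atol=1e-8)

    def test_full_rank_zero_residual(self, dx_random):
        k = np.linalg.matrix_rank(dx_random.rows)
        wm = dw.delta_pca(dx_random, k)
        assert dw.reconstruction_residual(wm, dx_random) < 1e-8

    def test_rank_error(self, dx_random):
        with pytest.raises(ValueError):
            dw.delta_pca(dx_random, 7)


class TestDeltaSD:
    def test_objective_monotone(self, dx_random):
        lam = 0.5
        objs = []
        for n_iter in range(1, 6):
            wm, C = dw.delta_sd(dx_random, 3, lam, n_iter=n_iter, seed=0)
            objs.append(dw._sd_objective(dx_random.rows, C.C, wm.W, lam))
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-8)

    def test_lambda_zero_full_rank(self, rng):
        rows = rng.normal(size=(30, 4))
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((30, 2), int),
                                seed=0)
        wm, C = dw.delta_sd(d, 4, 0.0, n_iter=30, seed=1)
        resid = np.sum((rows - C.C @ wm.W) ** 2)
        assert resid < 1e-6 * np.sum(rows**2)

    def test_huge_lambda_kills_coefficients(self, dx_random):
        wm, C = dw.delta_sd(dx_random, 3, 1e6, n_iter=3, seed=0)
        assert np.abs(C.C).max() < 1e-8

    def test_unit_rows(self, dx_random):
        wm, _ = dw.delta_sd(dx_random, 3, 0.2, n_iter=5, seed=0)
        np.testing.assert_allclose(np.linalg.norm(wm.W, axis=1), 1.0,
                                   atol=1e-10)

    def test_negative_lambda_rejected(self, dx_random):
        with pytest.raises(ValueError):
            dw.delta_sd(dx_random, 2, -0.1)

    def test_deterministic(self, dx_random):
        a, _ = dw.delta_sd(dx_random, 3, 0.3, n_iter=4, seed=9)
        b, _ = dw.delta_sd(dx_random, 3, 0.3, n_iter=4, seed=9)
        np.testing.assert_array_equal(a.W, b.W)


class TestDeltaPMD:
    def test_constraints_satisfied(self, dx_random):
        eps, delta = 1.5, 2.0
        wm, C = dw.delta_pmd(dx_random, 3, eps, delta)
        assert np.all(np.linalg.norm(wm.W, axis=1) <= 1 + 1e-6)
        assert np.all(np.abs(wm.W).sum(axis=1) <= eps + 1e-6)
        # coefficient columns are scaled unit-L2 left factors; the L1
        # bound applies to the direction
        norms = np.linalg.norm(C.C, axis=0)
        norms[norms == 0] = 1.0
        assert np.all(np.abs(C.C / norms).sum(axis=0) <= delta + 1e-6)

    def test_noop_bounds_reduce_to_svd(self, rng):
        rows = rng.normal(size=(15, 6))
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((15, 2), int),
                                seed=0)
        wm, _ = dw.delta_pmd(d, 2, eps=np.sqrt(6), delta=np.sqrt(15))
        _, _, Vt = np.linalg.svd(rows)
        for r in range(2):
            assert abs(wm.W[r] @ Vt[r]) > 1 - 1e-6

    def test_rank_one_sparse_recovery(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.zeros(8)
        v[2], v[5] = 3.0, 4.0
        rows = np.outer(u, v)
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((4, 2), int),
                                seed=0)
        vn = v / np.linalg.norm(v)
        eps = np.abs(vn).sum() + 0.1
        wm, _ = dw.delta_pmd(d, 1, eps=eps, delta=4.0)
        assert abs(wm.W[0] @ vn) > 1 - 1e-6

    def test_infeasible_constraints_rejected(self, dx_random):
        with pytest.raises(ValueError):
            dw.delta_pmd(dx_random, 2, eps=0.5, delta=2.0)
        with pytest.raises(ValueError):
            dw.delta_pmd(dx_random, 2, eps=2.0, delta=0.9)


class TestRandomProjection:
    def test_seed_behaviour(self):
        a = dw.random_projection(10, 4, seed=1)
        b = dw.random_projection(10, 4, seed=1)
        c = dw.random_projection(10, 4, seed=2)
        np.testing.assert_array_equal(a.W, b.W)
        assert not np.array_equal(a.W, c.W)

    def test_moments(self):
        wm = dw.random_projection(200, 300, seed=0)
        assert abs(wm.W.mean()) < 0.005
        np.testing.assert_allclose(wm.W.var(), 1.0 / 200, rtol=0.05)

    def test_k_zero(self):
        wm = dw.random_projection(5, 0, seed=0)
        assert wm.W.shape == (0, 5)


class TestReconstructionResidual:
    def test_spanning_rows_zero_residual(self, rng):
        W = dw.WeightMatrix(W=np.eye(4), method="rp")
        rows = rng.normal(size=(10, 4))
        d = dw.DifferenceMatrix(rows=rows, pair_index=np.zeros((10, 2), int),
                                seed=0)
        assert dw.reconstruction_residual(W, d) < 1e-8

    def test_equals_discarded_singular_values(self, dx_random):
        s = np.linalg.svd(dx_random.rows, compute_uv=False)
        for k in (1, 2, 3):
            wm = dw.delta_pca(dx_random, k)
            expected = float(np.sum(s[k:] ** 2))
            assert abs(dw.reconstruction_residual(wm, dx_random) - expected) \
                < 1e-6

    def test_monotone_in_rows(self, dx_random):
        full = dw.delta_pca(dx_random, 4).W
        resids = []
        for k in range(1, 5):
            wm = dw.WeightMatrix(W=full[:k], method="dpca")
            resids.append(dw.reconstruction_residual(wm, dx_random))
        assert np.all(np.diff(resids) <= 1e-10)

    def test_empty_matrix(self, dx_random):
        wm = dw.WeightMatrix(W=np.zeros((0, 6)), method="rp")
        assert dw.reconstruction_residual(wm, dx_random) == pytest.approx(
            np.sum(dx_random.rows**2))


class TestOptimalityProperties:
    def test_dpca_beats_random_rank_k(self, dx_random, rng):
        k = 2
        best = dw.reconstruction_residual(dw.delta_pca(dx_random, k),
                                          dx_random)
        for _ in range(100):
            W = dw.WeightMatrix(W=rng.normal(size=(k, 6)), method="rp")
            assert best <= dw.reconstruction_residual(W, dx_random) + 1e-8

    def test_constrained_methods_above_dpca(self, dx_random):
        k = 3
        base = dw.reconstruction_residual(dw.delta_pca(dx_random, k),
                                          dx_random)
        wm_sd, _ = dw.delta_sd(dx_random, k, 0.5, n_iter=5, seed=0)
        wm_pmd, _ = dw.delta_pmd(dx_random, k, eps=1.5, delta=2.0)
        assert dw.reconstruction_residual(wm_sd, dx_random) >= base - 1e-8
        assert dw.reconstruction_residual(wm_pmd, dx_random) >= base - 1e-8


class TestPersistence:
    def test_npz_roundtrip(self, tmp_path, dx_random):
        wm = dw.delta_pca(dx_random, 2)
        wm.save(tmp_path / "w.npz")
        loaded = dw.WeightMatrix.load(tmp_path / "w.npz")
        np.testing.assert_array_equal(loaded.W, wm.W)
        assert loaded.method == "dpca"
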