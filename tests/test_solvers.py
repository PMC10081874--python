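import numpy as np
import pytest

from conftest import random_endmembers
from slpru import (
    DimensionError,
    SolverConfig,
    l21_norm,
    nls_pixel,
    slnls_window,
    snls_window,
    solve_window_slpru,
    update_weights,
)
from slpru.solvers import nls_batch, solve_windows_batch


class TestUpdateWeights:
    def test_zero_row_gets_max_weight(self):
        A = np.zeros((3, 9))
        A[0] = 2.0
        A[1] = 1.0
        w = update_weights(A, eps_scale=1e-3)
        norms = np.linalg.norm(A, axis=1)
        eps_q = 1e-3 * norms.max()
        assert w.wq[2] == pytest.approx(1.0 / eps_q)
        assert w.wq[2] == w.wq.max()

    def test_scale_leaves_weight_ratios(self, rng):
        A = rng.random((4, 9))
        w1 = update_weights(A)
        w2 = update_weights(5.0 * A)
        assert np.allclose(w1.wq / w1.wq[0], w2.wq / w2.wq[0], rtol=1e-10)

    def test_diag_hand_evaluation(self):
        A = np.zeros((2, 9))
        A[0, 0] = 3.0
        A[1, 1] = 1.0
        w = update_weights(A, eps_scale=1e-3)
        eps_p = 1e-3 * 3.0
        assert np.allclose(w.wp, [1 / (3 + eps_p), 1 / (1 + eps_p)])

    def test_wp_non_decreasing(self, rng):
        w = update_weights(rng.random((5, 9)))
        assert np.all(np.diff(w.wp) >= -1e-12)


class TestNls:
    def test_exact_interior(self, rng):
        M = random_endmembers(rng, 6, 3)
        a_true = rng.uniform(0.5, 2.0, 3)
        a = nls_pixel(M.M @ a_true, M)
        assert np.allclose(a, a_true, atol=1e-8)

    def test_active_constraint(self):
        # unconstrained optimum (-1, 1) is infeasible; KKT at (0, 0.5)
        M = np.array([[1.0, 1.0], [0.0, 1.0]])
        a = nls_pixel(np.array([0.0, 1.0]), M)
        assert np.allclose(a, [0.0, 0.5], atol=1e-10)

    def test_zero_input(self, rng):
        M = random_endmembers(rng, 4, 2)
        assert np.allclose(nls_pixel(np.zeros(4), M), 0.0)

    def test_kkt_residual(self, rng):
        M = random_endmembers(rng, 8, 4)
        y = rng.random(8)
        a = nls_pixel(y, M)
        g = M.M.T @ (M.M @ a - y)
        # gradient ~ 0 on active entries, >= 0 on zero entries
        assert np.all(g >= -1e-8)
        assert np.all(np.abs(g[a > 1e-12]) < 1e-8)

    def test_batch_matches_pixelwise(self, rng):
        M = random_endmembers(rng, 5, 3)
        Y = rng.random((2, 5, 4))
        A = nls_batch(Y, M)
        for b in range(2):
            for n in range(4):
                assert np.allclose(A[b, :, n], nls_pixel(Y[b, :, n], M), atol=1e-10)


class TestSlpruWindow:
    def test_zero_window_gives_zero(self, rng):
        M = random_endmembers(rng, 6, 3)
        cfg = SolverConfig(lambda1=0.5, lambda2=0.5, mu=0.1, max_iter=500)
        res = solve_window_slpru(np.zeros((6, 9)), M, cfg)
        assert np.allclose(res.A.A, 0.0, atol=1e-6)

    def test_noiseless_recovery_lambda_zero(self, rng):
        M = random_endmembers(rng, 8, 4)
        A_true = rng.uniform(0.2, 2.0, (4, 9))
        Y = M.M @ A_true
        cfg = SolverConfig(lambda1=0, lambda2=0, mu=0.1, tol=1e-10, max_iter=5000)
        res = solve_window_slpru(Y, M, cfg)
        rel = np.linalg.norm(res.A.A - A_true) / np.linalg.norm(A_true)
        assert rel < 1e-3

    def test_shape_error(self, rng):
        M = random_endmembers(rng, 6, 3)
        with pytest.raises(DimensionError):
            solve_window_slpru(np.zeros((5, 9)), M, SolverConfig())

    def test_deterministic(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.poisson(5.0, (6, 9)).astype(float)
        cfg = SolverConfig(lambda1=0.1, lambda2=0.1, mu=0.1, max_iter=200)
        r1 = solve_window_slpru(Y, M, cfg)
        r2 = solve_window_slpru(Y, M, cfg)
        assert np.array_equal(r1.A.A, r2.A.A)
        assert r1.objective == r2.objective

    def test_result_invariants(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.poisson(3.0, (6, 9)).astype(float)
        cfg = SolverConfig(lambda1=0.05, lambda2=0.05, mu=0.1, max_iter=300)
        res = solve_window_slpru(Y, M, cfg)
        assert np.all(res.A.A >= 0)
        assert res.primal_residual >= 0 and res.dual_residual >= 0
        assert res.iterations <= cfg.max_iter * cfg.outer_reweights


class TestBaselines:
    def test_snls_lambda_zero_is_pixelwise_nls(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.random((6, 9)) * 3
        cfg = SolverConfig(mu=0.5, tol=1e-10, max_iter=5000)
        A = snls_window(Y, M, 0.0, cfg=cfg).A
        for n in range(9):
            assert np.allclose(A[:, n], nls_pixel(Y[:, n], M), atol=1e-6)

    def test_snls_huge_lambda_zeroes(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.random((6, 9))
        lam = 1e6 * np.linalg.norm(M.M.T @ Y)
        A = snls_window(Y, M, lam, cfg=SolverConfig(mu=1.0, max_iter=2000)).A
        assert np.allclose(A, 0.0, atol=1e-6)

    def test_slnls_lambda_zero_is_pixelwise_nls(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.random((6, 9)) * 2
        cfg = SolverConfig(mu=0.5, tol=1e-10, max_iter=5000)
        A = slnls_window(Y, M, 0.0, 0.0, cfg=cfg).A
        for n in range(9):
            assert np.allclose(A[:, n], nls_pixel(Y[:, n], M), atol=1e-6)

    def test_slnls_rank1_promotion(self, rng):
        M = random_endmembers(rng, 8, 4)
        a_col = rng.uniform(0.5, 1.5, 4)
        A_true = np.outer(a_col, rng.uniform(0.5, 1.0, 9))  # rank-1 truth
        Y = M.M @ A_true
        cfg = SolverConfig(mu=0.5, tol=1e-10, max_iter=4000)
        A = slnls_window(Y, M, 0.05, 0.0, cfg=cfg).A
        s = np.linalg.svd(A, compute_uv=False)
        assert s[1] / s[0] < 1e-3

    def test_l21_monotone_in_lambda2(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.poisson(4.0, (6, 9)).astype(float)
        cfg = SolverConfig(mu=0.5, max_iter=1000)
        norms = []
        for lam in [0, 1e-3, 1e-2, 1e-1, 1, 10]:
            norms.append(l21_norm(snls_window(Y, M, lam, cfg=cfg).A))
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))


class TestBatchInterface:
    def test_batch_matches_single(self, rng):
        M = random_endmembers(rng, 6, 3)
        Y = rng.poisson(4.0, (3, 6, 9)).astype(float)
        cfg = SolverConfig(lambda1=0.1, lambda2=0.1, mu=0.2, max_iter=300)
        A_batch, _ = solve_windows_batch(Y, M, "slpru", cfg)
        for b in range(3):
            single = solve_window_slpru(Y[b], M, cfg)
            assert np.allclose(A_batch[b], single.A.A, atol=1e-8)

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError):
            solve_windows_batch(np.ones((1, 2, 9)), np.ones((2, 2)) / 2, "qp",
                                SolverConfig())

    def test_channel_mismatch(self, rng):
        M = random_endmembers(rng, 6, 3)
        with pytest.raises(DimensionError):
            solve_windows_batch(np.ones((1, 5, 9)), M, "slpru", SolverConfig())
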