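import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import l21_loop, pad_then_slice_window, poisson_nll_loop
from slpru import (
    DegenerateInputError,
    DimensionError,
    DomainError,
    EndmemberMatrix,
    SolverConfig,
    SpectralImage,
    Window,
    extract_windows,
    l21_norm,
    poisson_nll,
    weighted_nuclear_norm,
    windows_array,
)


class TestSpectralImage:
    def test_valid(self):
        img = SpectralImage(np.ones((3, 4, 5)))
        assert (img.C, img.H, img.W) == (3, 4, 5)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            SpectralImage(-np.ones((2, 2, 2)))

    def test_wrong_rank_rejected(self):
        with pytest.raises(DimensionError):
            SpectralImage(np.ones((4, 5)))

    def test_channel_centers_length(self):
        with pytest.raises(DimensionError):
            SpectralImage(np.ones((3, 2, 2)), channel_centers=np.arange(2))

    def test_flatten_is_row_major(self):
        cube = np.arange(12.0).reshape(1, 3, 4)
        assert np.array_equal(SpectralImage(cube).flatten()[0], np.arange(12.0))


class TestEndmemberMatrix:
    def test_unit_sum_enforced(self):
        with pytest.raises(DomainError):
            EndmemberMatrix(np.ones((4, 2)))

    def test_from_columns_normalizes(self):
        M = EndmemberMatrix.from_columns(np.ones((4, 2)))
        assert np.allclose(M.M.sum(axis=0), 1.0)
        assert M.names == ["EM01", "EM02"]

    def test_zero_column_rejected(self):
        M = np.ones((3, 2))
        M[:, 1] = 0.0
        with pytest.raises(DegenerateInputError):
            EndmemberMatrix.from_columns(M)


class TestSolverConfig:
    def test_defaults(self):
        cfg = SolverConfig()
        assert cfg.mu == 0.01 and cfg.max_iter == 2000 and cfg.outer_reweights == 2

    @pytest.mark.parametrize(
        "kw", [{"mu": 0}, {"tol": -1}, {"max_iter": 0}, {"lambda1": -0.1},
               {"outer_reweights": 0}, {"eps_scale": 0}]
    )
    def test_invalid(self, kw):
        with pytest.raises(DomainError):
            SolverConfig(**kw)


class TestPoissonNll:
    def test_log1_is_zero(self):
        # each term is 1 - 1*log 1 = 1
        assert poisson_nll([[1.0], [1.0]], [[1.0]], [[1.0], [1.0]]) == pytest.approx(2.0)

    def test_zero_counts_convention(self):
        # 0*log 0 = 0: fidelity reduces to sum(MA)
        assert poisson_nll([[1.0], [1.0]], [[1.0]], [[0.0], [0.0]]) == pytest.approx(2.0)

    def test_matches_loop_oracle(self):
        M, A, Y = [[1.0], [1.0]], [[2.0]], [[2.0], [0.0]]
        assert poisson_nll(M, A, Y) == pytest.approx(poisson_nll_loop(M, A, Y))

    def test_matches_loop_oracle_random(self, rng):
        M = rng.random((5, 3))
        A = rng.random((3, 7))
        Y = rng.poisson(3.0, (5, 7)).astype(float)
        assert poisson_nll(M, A, Y) == pytest.approx(
            poisson_nll_loop(M, A, Y), rel=1e-12
        )

    def test_plug_in_identity(self, rng):
        # with Y = MA exactly: nll = sum(MA) - sum(Y log Y)
        M = rng.uniform(0.1, 1, (6, 3))
        A = rng.uniform(0.1, 2, (3, 4))
        Y = M @ A
        expected = Y.sum() - np.sum(Y * np.log(Y))
        assert poisson_nll(M, A, Y) == pytest.approx(expected, rel=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            poisson_nll(np.ones((2, 2)), np.ones((3, 2)), np.ones((2, 2)))

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            poisson_nll(np.ones((2, 1)), np.ones((1, 1)), -np.ones((2, 1)))


class TestNorms:
    def test_l21_345(self):
        assert l21_norm([[3.0, 4.0], [0.0, 0.0]]) == pytest.approx(5.0)

    def test_l21_identity(self):
        assert l21_norm(np.eye(2)) == pytest.approx(2.0)

    def test_l21_loop_oracle(self, rng):
        A = rng.standard_normal((5, 9))
        assert l21_norm(A) == pytest.approx(l21_loop(A), rel=1e-12)

    def test_wnn_uniform(self):
        assert weighted_nuclear_norm(np.diag([3.0, 1.0]), [1, 1]) == pytest.approx(4.0)

    def test_wnn_weighted(self):
        assert weighted_nuclear_norm(np.diag([3.0, 1.0]), [1, 2]) == pytest.approx(5.0)

    def test_wnn_svd_oracle(self, rng):
        A = rng.standard_normal((4, 9))
        expected = sum(np.linalg.svd(A, compute_uv=False))
        assert weighted_nuclear_norm(A, np.ones(4)) == pytest.approx(expected)

    def test_wnn_negative_weight(self):
        with pytest.raises(DomainError):
            weighted_nuclear_norm(np.eye(2), [-1, 1])

    @settings(max_examples=25, deadline=None)
    @given(
        A=arrays(float, (4, 6), elements=st.floats(-5, 5)),
        c=st.floats(0, 10),
    )
    def test_absolute_homogeneity(self, A, c):
        assert l21_norm(c * A) == pytest.approx(c * l21_norm(A), abs=1e-8)
        assert weighted_nuclear_norm(c * A, np.ones(4)) == pytest.approx(
            c * weighted_nuclear_norm(A, np.ones(4)), abs=1e-7
        )


class TestWindows:
    def test_count_3x3(self):
        img = SpectralImage(np.arange(9.0).reshape(1, 3, 3))
        wins = list(extract_windows(img))
        assert len(wins) == 9
        center = wins[4]
        assert center.origin == (1, 1)
        assert np.array_equal(center.Y[0], np.arange(9.0))

    def test_count_5x4(self):
        img = SpectralImage(np.ones((2, 5, 4)))
        assert len(list(extract_windows(img))) == 20

    def test_corner_matches_pad_oracle(self, ramp_image):
        wins = windows_array(ramp_image)
        W = ramp_image.W
        for i in (0, W - 1, (ramp_image.H - 1) * W):
            expected = pad_then_slice_window(ramp_image.counts, i // W, i % W)
            assert np.array_equal(wins[i], expected)

    def test_interior_matches_im2col(self, ramp_image):
        wins = windows_array(ramp_image)
        cube = ramp_image.counts
        for r in range(1, ramp_image.H - 1):
            for c in range(1, ramp_image.W - 1):
                patch = cube[:, r - 1 : r + 2, c - 1 : c + 2].reshape(cube.shape[0], 9)
                assert np.array_equal(wins[r * ramp_image.W + c], patch)

    def test_window_invariants(self):
        with pytest.raises(DimensionError):
            Window(Y=np.ones((2, 8)), origin=(0, 0))
        with pytest.raises(DomainError):
            Window(Y=np.ones((2, 9)), origin=(0, 0), center_index=3)
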