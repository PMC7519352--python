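"""Sensitivity matrix assembly: Born-sum oracle, structure, depth weighting."""

import numpy as np
import pytest

from flotsim import (
    AcquisitionSpec,
    FluenceField,
    GreenField,
    SlabForwardModel,
    SourceSpec,
    VoxelGrid,
    build_weight_matrix,
    build_weight_matrix_conv,
    depth_compensate,
    make_homogeneous_medium,
    slab_response_kernels,
)
from flotsim.mc import SlabKernels


def _integer_fields(grid, n_pos, offsets, seed=0):
    """Integer-valued synthetic fields make the Born sum exact in float64."""
    rng = np.random.default_rng(seed)
    phis = [
        FluenceField(grid, rng.integers(0, 9, grid.shape).astype(float))
        for _ in range(n_pos)
    ]
    greens = {
        d: GreenField(grid, rng.integers(0, 9, grid.shape).astype(float))
        for d in offsets
    }
    return phis, greens


class TestExplicitAssembly:
    def test_single_voxel_grid_gives_scalar_product(self):
        grid = VoxelGrid(1, 1, 1, 0.5)
        phis = [FluenceField(grid, np.full(grid.shape, 3.0))]
        greens = {0: GreenField(grid, np.full(grid.shape, 2.0))}
        W = build_weight_matrix(phis, greens, grid)
        assert W.shape == (1, 1)
        assert W.matrix[0, 0] == pytest.approx(3.0 * 2.0 * 0.5**3)

    def test_matvec_equals_brute_force_born_sum_exactly(self):
        # triple-sum oracle: frame(s, d) = sum_v G_d(v) O(v) Phi_s(v) dV
        grid = VoxelGrid(4, 4, 4, 0.25)
        offsets = [1, 2]
        phis, greens = _integer_fields(grid, 3, offsets)
        W = build_weight_matrix(phis, greens, grid, offsets, floor_rel=0.0)
        rng = np.random.default_rng(5)
        O = rng.integers(0, 5, grid.shape).astype(float)
        got = W.matvec(O.ravel())
        vv = grid.voxel_volume
        for s in range(3):
            for d in offsets:
                expected = 0.0
                for i in range(4):
                    for j in range(4):
                        for k in range(4):
                            expected += (
                                greens[d].green[i, j, k]
                                * O[i, j, k]
                                * phis[s].phi[i, j, k]
                                * vv
                            )
                assert got[W.row_index[(s, d)]] == expected

    def test_missing_green_offset_rejected(self):
        grid = VoxelGrid(2, 2, 2, 0.1)
        phis, greens = _integer_fields(grid, 1, [1])
        with pytest.raises(ValueError, match=r"missing Green.*\[2\]"):
            build_weight_matrix(phis, greens, grid, offsets=[1, 2])

    def test_entries_nonnegative(self):
        grid = VoxelGrid(3, 3, 3, 0.1)
        phis, greens = _integer_fields(grid, 2, [1, 2], seed=8)
        W = build_weight_matrix(phis, greens, grid)
        assert (W.matrix < 0).nnz == 0


@pytest.fixture(scope="module")
def conv_model():
    grid = VoxelGrid(40, 8, 30, 0.02)
    med = make_homogeneous_medium(grid, 0.01, 15.0, 0.9, 1.33)
    src = SourceSpec(kind="line", incidence_deg=135.0, line_fwhm=0.02)
    kk = slab_response_kernels(med, src, 300_000, 17, nu_half=30, nfx=61,
                               nfy=8, nz=30)
    # offsets kept below the scoring depth (0.6 mm): the mean-depth trend
    # saturates once the probed depth reaches the grid bottom
    return SlabForwardModel(kk, grid, np.arange(1, 21))


class TestConvolutionalBackend:
    def test_adjoint_identity(self, conv_model, rng):
        x = rng.random(conv_model.grid.shape)
        y = rng.random(conv_model.measurement_shape)
        lhs = float(np.vdot(y, conv_model.forward(x)))
        rhs = float(np.vdot(conv_model.adjoint(y), x))
        assert lhs == pytest.approx(rhs, rel=1.0e-10)

    def test_rows_translate_with_stage_position(self, conv_model):
        # a point object shifted by dx voxels yields measurements shifted
        # by dx stage positions (block-convolutional structure), exactly
        O = np.zeros(conv_model.grid.shape)
        O[10, 4, 5] = 1.0
        f1 = conv_model.forward(O)
        O2 = np.roll(O, 7, axis=0)
        f2 = conv_model.forward(O2)
        np.testing.assert_allclose(
            f2[7:30], f1[:23], rtol=1.0e-9, atol=1.0e-12 * float(f1.max())
        )

    def test_forward_matches_explicit_kernel_sum(self, conv_model, rng):
        # FFT path against a direct dense correlation on one offset
        O = rng.random(conv_model.grid.shape)
        F = conv_model.forward(O)
        d_idx = 3
        kd = conv_model.kernel(int(conv_model.offsets_vox[d_idx]))
        U = conv_model.kernels.nu_half
        V = conv_model.grid.ny - 1
        s, yb = 20, 4
        expected = 0.0
        for u in range(-U, U + 1):
            if not (0 <= s + u < conv_model.grid.nx):
                continue
            for v in range(-V, V + 1):
                if not (0 <= yb + v < conv_model.grid.ny):
                    continue
                expected += float(
                    kd[u + U, v + V] @ O[s + u, yb + v]
                )
        assert F[s, d_idx, yb] == pytest.approx(expected, rel=1.0e-10)

    def test_mean_sensitivity_depth_increases_with_offset(self, conv_model):
        # wider source-detector separations probe deeper
        depths = conv_model.mean_sensitivity_depth()
        assert np.all(np.diff(depths) > 0)

    def test_no_measurement_blind_to_tissue(self, conv_model):
        W = build_weight_matrix_conv(conv_model)
        ones = np.ones(W.shape[1])
        assert np.all(W.matvec(ones) > 0)


class TestDepthCompensation:
    def _toy(self):
        # 2-layer system with known entries
        grid = VoxelGrid(2, 1, 2, 1.0)
        W = np.array(
            [
                [4.0, 1.0, 0.5, 0.2],
                [2.0, 3.0, 0.3, 0.4],
                [1.0, 0.5, 0.25, 0.1],
            ]
        )
        # columns ordered (x, y, z) C-style: z fastest -> cols 0,2 are layer 0
        import scipy.sparse as sp

        from flotsim.sensitivity import SensitivityMatrix

        return SensitivityMatrix(grid, "sparse", matrix=sp.csr_matrix(W))

    def test_gamma_zero_is_identity(self):
        W = self._toy()
        out = depth_compensate(W, 0.0)
        assert out is W

    def test_layer_maxima_match_svd_oracle_and_columns_scale(self):
        W = self._toy()
        out = depth_compensate(W, 1.0)
        dense = W.matrix.toarray()
        # cumulative submatrices: layer 1 = z index 0 columns, layer 2 = all
        m1 = np.linalg.svd(dense[:, [0, 2]], compute_uv=False)[0]
        m2 = np.linalg.svd(dense, compute_uv=False)[0]
        np.testing.assert_allclose(out.depth_weights, [m1, m2], rtol=1e-10)
        x = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(out.matvec(x), dense[:, 0] * m1, rtol=1e-10)

    def test_deeper_weighting_grows_with_gamma(self):
        W = self._toy()
        w1 = depth_compensate(W, 1.0)
        w2 = depth_compensate(W, 2.0)

        def deep_to_shallow(M):
            cn = M.column_norm_by_layer()
            return cn[-1] / cn[0]

        base = deep_to_shallow(W)
        assert deep_to_shallow(w2) > deep_to_shallow(w1) >= base

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            depth_compensate(self._toy(), 3.5)

    def test_all_zero_layer_rejected(self):
        import scipy.sparse as sp

        from flotsim.sensitivity import SensitivityMatrix

        grid = VoxelGrid(2, 1, 2, 1.0)
        W = np.array([[1.0, 0.0, 2.0, 0.0], [0.5, 0.0, 1.0, 0.0]])
        sm = SensitivityMatrix(grid, "sparse", matrix=sp.csr_matrix(W))
        with pytest.raises(ValueError, match="layer"):
            depth_compensate(sm, 1.0)
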