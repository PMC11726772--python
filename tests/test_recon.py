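"""LLR proximal operator, temporal subspace, DCF, and the PDPS solver."""

import numpy as np
import pytest

import radrelax as rr
from radrelax.recon import (block_nuclear_norm, block_ranks, cell_volume_weights,
                            density_compensation, llr_prox, RadialFrameOperator)
from radrelax.signal_models import sat_recovery_signal


def svt_oracle(mat, thresh):
    """Independent singular-value soft-threshold on one unfolded block."""
    U, s, Vh = np.linalg.svd(mat, full_matrices=False)
    return U @ np.diag(np.maximum(s - thresh, 0.0)) @ Vh


class TestLlrProx:
    def test_zero_lambda_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8, 8, 4))
        out = llr_prox(x, 0.0, 8)
        assert out is x  # bit-identical, not a copy

    def test_full_shrinkage_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 8, 8, 3))
        big = np.linalg.svd(x.reshape(512, 3), compute_uv=False)[0] * 1.01
        assert np.allclose(llr_prox(x, big, 8), 0.0)

    def test_single_block_matches_svt_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 8, 8, 4)) + 1j * rng.standard_normal((8, 8, 8, 4))
        out = llr_prox(x, 0.5, 8)
        expect = svt_oracle(x.reshape(512, 4), 0.5).reshape(8, 8, 8, 4)
        assert np.allclose(out, expect, atol=1e-10)

    def test_multi_block_matches_per_block_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((16, 8, 8, 3))
        out = llr_prox(x, 0.7, 8)
        for sl in (slice(0, 8), slice(8, 16)):
            expect = svt_oracle(x[sl].reshape(512, 3), 0.7).reshape(8, 8, 8, 3)
            assert np.allclose(out[sl], expect, atol=1e-10)

    def test_edge_blocks_zero_padded(self):
        # 12^3 grid with block 8: padded blocks must reproduce the oracle
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 12, 12, 2))
        out = llr_prox(x, 0.3, 8)
        pad = np.zeros((16, 16, 16, 2))
        pad[:12, :12, :12] = x
        blk = pad[:8, :8, :8].reshape(512, 2)
        assert np.allclose(out[:8, :8, :8],
                           svt_oracle(blk, 0.3).reshape(8, 8, 8, 2), atol=1e-10)

    def test_nonexpansive(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.standard_normal((8, 8, 8, 4))
            b = rng.standard_normal((8, 8, 8, 4))
            pa, pb = llr_prox(a, 0.4, 8), llr_prox(b, 0.4, 8)
            assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-12

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            llr_prox(np.zeros((8, 8, 8)), 0.1, 8)


class TestSubspace:
    def _times(self):
        proto = rr.t1_protocol(matrix=16)
        return proto, rr.bin_looklocker_frames(proto).frame_times

    def test_complete_basis_has_zero_projection_error(self):
        proto, t = self._times()
        grid = np.geomspace(0.1, 5.0, 40)
        basis = rr.build_subspace(proto, t, grid, K=t.size,
                                  efficiency_grid=(1.0,))
        c = sat_recovery_signal(t, 1.0, 1.0, 0.7)
        c /= np.linalg.norm(c)
        proj = basis.basis @ (basis.basis.T @ c)
        assert np.linalg.norm(c - proj) < 1e-10

    def test_identical_curves_are_rank_one(self):
        proto, t = self._times()
        basis = rr.build_subspace(proto, t, np.full(10, 0.5), K=2,
                                  efficiency_grid=(1.0,))
        assert basis.singular_values[1] < 1e-10

    def test_dictionary_residual_spectrum(self):
        # brute-force SVD oracle over the 200-point log-grid dictionary
        proto, t = self._times()
        grid = np.geomspace(0.1, 5.0, 200)
        for K, bound in ((5, 2e-3), (6, 5e-4)):
            basis = rr.build_subspace(proto, t, grid, K=K, efficiency_grid=(1.0,))
            P = basis.basis @ basis.basis.T
            res = 0.0
            for T in grid:
                c = sat_recovery_signal(t, 1.0, 1.0, T)
                c /= np.linalg.norm(c)
                res = max(res, np.linalg.norm(c - P @ c))
            assert res < bound

    def test_projection_idempotent(self):
        proto, t = self._times()
        basis = rr.build_subspace(proto, t, np.geomspace(0.1, 5, 30), K=5)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((t.size, 4))
        p1 = basis.expand(basis.project(x))
        p2 = basis.expand(basis.project(p1))
        assert np.allclose(p1, p2, atol=1e-10)

    def test_rank_exceeding_frames_rejected(self):
        proto, t = self._times()
        with pytest.raises(ValueError):
            rr.build_subspace(proto, t, np.geomspace(0.1, 5, 40), K=t.size + 1)


class TestDensityCompensation:
    def _spokes(self, spf=804, S=16):
        proto = rr.t1rho_protocol(matrix=16, spokes_per_frame=spf,
                                  tsl_list=(0, 4), samples_per_spoke=S)
        return proto, rr.make_t1rho_spokes(proto)

    def test_center_weight_minimal_positive(self):
        proto, spokes = self._spokes()
        w = density_compensation(spokes, proto.samples_per_spoke)
        assert w[0, 0] > 0
        assert w[0, 0] == w.min()

    def test_k_squared_law(self):
        proto, spokes = self._spokes()
        w = cell_volume_weights(spokes, proto.samples_per_spoke)
        # doubling the radius quadruples the cell volume (up to O((dr/r)^2))
        assert w[0, 8] / w[0, 4] == pytest.approx(4.0, rel=0.02)

    def test_delta_round_trip_amplitude(self):
        proto, spokes = self._spokes()
        N = proto.matrix
        op = RadialFrameOperator(spokes, proto)
        delta = np.zeros((N, N, N), dtype=complex)
        delta[N // 2, N // 2, N // 2] = 1.0
        y = op.forward(np.stack([delta, delta]))
        w = density_compensation(spokes, proto.samples_per_spoke)
        rec = op.adjoint(w * y)
        amp = abs(rec[0, N // 2, N // 2, N // 2])
        assert 0.9 <= amp <= 1.1


class TestPdps:
    def test_zero_data_gives_zero_image(self, t1rho_sim16):
        _, ks = t1rho_sim16
        ks0 = rr.RadialKSpace(samples=np.zeros_like(ks.samples), spokes=ks.spokes,
                              protocol=ks.protocol)
        op = rr.make_operator(ks0)
        cfg = rr.ReconConfig(llr_lambda=100.0, iterations=10)
        series, info = rr.pdps_solve(ks0, op, cfg, mode="framewise_t1rho")
        assert np.allclose(series.frames, 0.0)

    def test_objective_never_exceeds_initial(self, t1rho_sim16):
        _, ks = t1rho_sim16
        op = rr.make_operator(ks)
        for lam in (0.0, 1000.0):
            cfg = rr.ReconConfig(llr_lambda=lam, iterations=15)
            _, info = rr.pdps_solve(ks, op, cfg, mode="framewise_t1rho")
            trace = info["objective_trace"]
            assert trace[-1] <= trace[0]

    def test_nuclear_norm_decreases_with_lambda(self, t1rho_sim16):
        # 3-point regularization ladder: stronger shrinkage, smaller penalty
        _, ks = t1rho_sim16
        op = rr.make_operator(ks)
        norms = []
        for lam in (0.0, 3000.0, 30000.0):
            cfg = rr.ReconConfig(llr_lambda=lam, iterations=25)
            series, _ = rr.pdps_solve(ks, op, cfg, mode="framewise_t1rho")
            norms.append(block_nuclear_norm(np.moveaxis(series.frames, 0, -1), 8))
        assert norms[0] >= norms[1] >= norms[2]
        assert norms[2] < norms[0]

    def test_subspace_mode_requires_subspace_operator(self, t1rho_sim16):
        _, ks = t1rho_sim16
        op = rr.make_operator(ks)
        with pytest.raises(ValueError, match="subspace"):
            rr.pdps_solve(ks, op, rr.ReconConfig(iterations=1), mode="subspace_t1")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            rr.ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            rr.ReconConfig(llr_lambda=-1.0)


class TestBlockRanks:
    def test_rank_counts_on_constructed_stack(self):
        # one rank-1 block plus one rank-3 block
        rng = np.random.default_rng(7)
        u = rng.standard_normal((512, 1)) @ rng.standard_normal((1, 4))
        r3 = rng.standard_normal((512, 3)) @ rng.standard_normal((3, 4))
        stack = np.concatenate([u.reshape(8, 8, 8, 4), r3.reshape(8, 8, 8, 4)])
        ranks = block_ranks(stack, 8)
        assert sorted(ranks.tolist()) == [1, 3]
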