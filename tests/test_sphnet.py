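"""Spectral convolutions, pooling, invariant readout, the risk network and
its hand-written gradients."""

import numpy as np
import pytest

from sphsurv import harmonics as har
from sphsurv.harmonics import (
    SphericalGrid,
    block_degree_mask,
    real_symmetrize,
    sht_forward,
    so3_integral,
    so3_real_symmetrize,
)
from sphsurv.sphnet import (
    NetConfig,
    RiskModel,
    gradient_check,
    invariant_readout,
    pack_coeffs_to_rows,
    s2_conv,
    so3_conv,
    spherical_pool,
)
from sphsurv.survival_stats import (
    SurvivalCohort,
    neg_log_partial_likelihood,
    partial_likelihood_gradient,
)


def _random_real_coeffs(rng, B):
    return real_symmetrize(rng.normal(size=B * B) + 1j * rng.normal(size=B * B))


class TestS2Conv:
    def test_constant_signal_and_filter(self):
        B = 8
        g = SphericalGrid(B)
        c, d = 1.3, -0.7
        fc = sht_forward(np.full(g.shape, c), g)
        pc = sht_forward(np.full(g.shape, d), g)
        out = s2_conv(fc, pc).real
        np.testing.assert_allclose(out, c * d * 4 * np.pi, atol=1e-9)

    def test_zero_filter_gives_zero(self):
        rng = np.random.default_rng(0)
        B = 8
        f = _random_real_coeffs(rng, B)
        out = s2_conv(f, np.zeros(B * B, dtype=complex))
        assert np.abs(out).max() == 0.0

    def test_matches_direct_numerical_integration(self):
        """Spectral correlation equals brute-force quadrature of its
        definition (psi * f)(R) = int f(w) conj(psi(R^-1 w)) dw."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        B = 8
        g = SphericalGrid(B)
        f = _random_real_coeffs(rng, B)
        p = _random_real_coeffs(rng, B)
        out = s2_conv(f, p, L=B).real
        fgrid = har.sht_inverse(f, g)
        dirs = g.directions().reshape(-1, 3)
        gp = SphericalGrid(B)
        scale = np.abs(out).max()
        for (ai, bj, ck) in [(0, 0, 0), (3, 5, 2), (7, 11, 1), (12, 2, 9)]:
            R = Rotation.from_euler(
                "ZYZ", [gp.phis[ai], gp.thetas[bj], gp.phis[ck]]
            ).as_matrix()
            rd = dirs @ R
            th = np.arccos(np.clip(rd[:, 2], -1, 1))
            ph = np.arctan2(rd[:, 1], rd[:, 0])
            Y = har.spherical_harmonic_values(B, th, ph)
            psir = (p @ Y).reshape(g.shape)
            ref = g.integrate(fgrid * np.conj(psir)).real
            assert abs(out[ai, bj, ck] - ref) / scale < 1e-5

    def test_equivariance_under_grid_polar_rotations(self):
        rng = np.random.default_rng(2)
        B = 8
        g = SphericalGrid(B)
        fmap = har.sht_inverse(_random_real_coeffs(rng, B), g)
        p = _random_real_coeffs(rng, B)
        out0 = s2_conv(sht_forward(fmap, g), p).real
        for k in (1, 5, 8):
            rolled = np.roll(fmap, k, axis=1)  # rotation by pi*k/B about z
            outk = s2_conv(sht_forward(rolled, g), p).real
            assert np.abs(outk - np.roll(out0, k, axis=0)).max() < 1e-6


class TestSO3Conv:
    def _random_signal(self, rng, L, grid_B):
        blocks = so3_real_symmetrize(
            (
                rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        return har.so3_synthesize(blocks, grid_B), blocks

    def test_identity_filter_scales_blocks(self):
        rng = np.random.default_rng(3)
        L = 4
        sig, blocks = self._random_signal(rng, L, L)
        eye = np.zeros((L, 2 * L - 1, 2 * L - 1), dtype=complex)
        c = L - 1
        for l in range(L):
            eye[l, c - l : c + l + 1, c - l : c + l + 1] = 0.5 * np.eye(2 * l + 1)
        out_blocks = har.so3_analyze(so3_conv(sig, eye), L)
        for l in range(L):
            expected = 8 * np.pi**2 / (2 * l + 1) * 0.5 * blocks[l]
            np.testing.assert_allclose(out_blocks[l], expected, atol=1e-9)

    def test_zero_signal(self):
        L = 4
        filt = np.ones((L, 2 * L - 1, 2 * L - 1), dtype=complex) * block_degree_mask(L)
        out = so3_conv(np.zeros((2 * L, 2 * L, 2 * L)), filt)
        assert np.abs(out).max() == 0.0

    def test_left_translation_equivariance(self):
        rng = np.random.default_rng(4)
        L = 4
        sig, _ = self._random_signal(rng, L, L)
        filt = so3_real_symmetrize(
            (
                rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        out0 = so3_conv(sig, filt)
        for k in (1, 3):
            out_shift = so3_conv(np.roll(sig, k, axis=0), filt)
            assert np.abs(out_shift - np.roll(out0, k, axis=0)).max() < 1e-6

    def test_matches_direct_group_integration(self):
        """Block-product correlation equals brute-force integration over the
        group: (Psi * g)(R) = int g(Q) conj(Psi(R^-1 Q)) dQ."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        L = 3
        grid_B = 4
        blocks = so3_real_symmetrize(
            (
                rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        filt = so3_real_symmetrize(
            (
                rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        sig = har.so3_synthesize(blocks, grid_B)
        out = so3_conv(sig, filt)

        def eval_blocks(blk, euler):
            val = 0.0 + 0j
            for l in range(L):
                d = har.wigner_d_matrices(l, [euler[1]])[0]
                m = np.arange(-l, l + 1)
                E = (
                    np.exp(1j * m[:, None] * euler[0])
                    * d
                    * np.exp(1j * m[None, :] * euler[2])
                )
                c = L - 1
                val += (blk[l, c - l : c + l + 1, c - l : c + l + 1] * E).sum()
            return val

        gq = SphericalGrid(grid_B)
        w = har.so3_weights(grid_B)
        scale = np.abs(out).max()
        for (ai, bj, ck) in [(0, 0, 0), (2, 3, 5)]:
            R = Rotation.from_euler(
                "ZYZ", [gq.phis[ai], gq.thetas[bj], gq.phis[ck]]
            ).as_matrix()
            ref = 0.0
            for a in range(2 * grid_B):
                for j in range(2 * grid_B):
                    for c in range(2 * grid_B):
                        Q = Rotation.from_euler(
                            "ZYZ", [gq.phis[a], gq.thetas[j], gq.phis[c]]
                        ).as_matrix()
                        e2 = Rotation.from_matrix(R.T @ Q).as_euler("ZYZ")
                        ref += w[j] * sig[a, j, c] * np.conj(eval_blocks(filt, e2))
            assert abs(out[ai, bj, ck] - ref) / scale < 1e-5


class TestPoolAndReadout:
    def test_pool_preserves_constants(self):
        sig = np.full((8, 8, 8), 2.2)
        out = spherical_pool(sig, 2)
        np.testing.assert_allclose(out, 2.2, atol=1e-10)
        assert out.shape == (4, 4, 4)

    def test_pool_exact_below_cutoff(self):
        rng = np.random.default_rng(6)
        L = 2
        grid_B = 4
        blocks = so3_real_symmetrize(
            (
                rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        sig = har.so3_synthesize(blocks, grid_B)
        pooled = spherical_pool(sig, 2)
        exact = har.so3_synthesize(blocks, grid_B // 2)
        np.testing.assert_allclose(pooled, exact, atol=1e-8)

    def test_pool_never_increases_energy(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=(8, 8, 8))
        def energy(s):
            return np.sqrt(so3_integral(s**2))
        assert energy(spherical_pool(sig, 2)) <= energy(
            har.so3_synthesize(har.so3_analyze(sig, 4), 4)
        ) + 1e-9

    def test_readout_constant(self):
        sig = np.full((3, 8, 8, 8), 1.5)
        feats = invariant_readout(sig)
        np.testing.assert_allclose(feats[:, 0], 1.5 * 8 * np.pi**2, atol=1e-9)

    def test_readout_zero(self):
        feats = invariant_readout(np.zeros((2, 8, 8, 8)))
        np.testing.assert_array_equal(feats, 0.0)

    def test_readout_invariant_under_alpha_shift(self):
        rng = np.random.default_rng(8)
        L = 4
        blocks = so3_real_symmetrize(
            (
                rng.normal(size=(2, L, 2 * L - 1, 2 * L - 1))
                + 1j * rng.normal(size=(2, L, 2 * L - 1, 2 * L - 1))
            )
            * block_degree_mask(L)
        )
        sig = har.so3_synthesize(blocks, L)
        f0 = invariant_readout(sig)
        f1 = invariant_readout(np.roll(sig, 3, axis=-3))
        np.testing.assert_allclose(f0, f1, atol=1e-6)


class TestRiskModel:
    def _coeffs(self, rng, n, B, cin=1):
        g = SphericalGrid(B)
        return sht_forward(rng.normal(size=(n, cin, 2 * B, 2 * B)), g)

    def test_zero_input_zero_biases_gives_zero(self):
        cfg = NetConfig(bandwidth=8, channels1=3, channels2=4, seed=0)
        model = RiskModel(cfg)
        model.params["out_b"][:] = 0.0
        coeffs = np.zeros((2, 1, 64), dtype=complex)
        np.testing.assert_allclose(model.forward(coeffs), 0.0, atol=1e-12)

    def test_rotation_invariance_grid_polar(self):
        rng = np.random.default_rng(9)
        B = 16
        g = SphericalGrid(B)
        cfg = NetConfig(bandwidth=B, seed=3)
        model = RiskModel(cfg)
        stride = cfg.exact_rotation_stride
        maps = rng.normal(size=(3, 1, 2 * B, 2 * B))
        h0 = model.forward(sht_forward(maps, g))
        for k in (stride, 3 * stride, B):
            hk = model.forward(sht_forward(np.roll(maps, k, axis=-1), g))
            assert np.abs(hk - h0).max() < 1e-4
        # off-lattice grid rotations are approximately invariant: the ReLU
        # outputs are not band-limited, so sub-lattice shifts leak slightly
        h1 = model.forward(sht_forward(np.roll(maps, 1, axis=-1), g))
        assert np.abs(h1 - h0).max() < 0.02 * max(np.abs(h0).max(), np.ptp(h0))

    def test_forward_matches_functional_composition(self):
        """The model's fused spectral path equals the literal op-by-op
        composition (conv -> ReLU -> pool -> conv -> ReLU -> pool -> readout)."""
        rng = np.random.default_rng(10)
        B = 8
        cfg = NetConfig(bandwidth=B, channels1=3, channels2=4, seed=4)
        model = RiskModel(cfg)
        coeffs = self._coeffs(rng, 2, B)
        h_model = model.forward(coeffs)

        psi, Psi = model._filters()
        L1, L2, L3 = cfg.L1, cfg.L2, cfg.L3
        h_ref = []
        for b in range(coeffs.shape[0]):
            # layer 1: S2 correlation summed over input channels
            grids = []
            for o in range(cfg.channels1):
                acc = 0
                for i in range(cfg.in_channels):
                    acc = acc + s2_conv(coeffs[b, i], psi[o, i], L=L1).real
                grids.append(acc + model.params["s2_bias"][o])
            r1 = np.maximum(np.stack(grids), 0.0)
            p1 = np.stack([spherical_pool(ch, 2) for ch in r1])
            # layer 2: SO(3) correlation
            grids2 = []
            for o in range(cfg.channels2):
                acc = 0
                for i in range(cfg.channels1):
                    acc = acc + so3_conv(p1[i], Psi[o, i])
                grids2.append(acc + model.params["so3_bias"][o])
            r2 = np.maximum(np.stack(grids2), 0.0)
            p2 = np.stack([spherical_pool(ch, 2) for ch in r2])
            feats = invariant_readout(p2)  # (c2, 2): integral, norm
            mean = feats[:, 0] / (8 * np.pi**2)
            rms = feats[:, 1] / np.sqrt(8 * np.pi**2)
            x = np.concatenate([mean, rms])
            d1 = model.params["dense_w"] @ x + model.params["dense_b"]
            h_ref.append(
                float(np.maximum(d1, 0) @ model.params["out_w"] + model.params["out_b"][0])
            )
        np.testing.assert_allclose(h_model, h_ref, atol=1e-8)

    def test_gradient_check_cox_loss(self):
        rng = np.random.default_rng(11)
        cfg = NetConfig(bandwidth=8, channels1=3, channels2=4, seed=1)
        model = RiskModel(cfg)
        coeffs = self._coeffs(rng, 4, 8)
        cohort = SurvivalCohort([3.0, 1.0, 4.0, 2.0], [1, 1, 0, 1])
        res = gradient_check(
            model,
            coeffs,
            lambda h: neg_log_partial_likelihood(h, cohort),
            lambda h: partial_likelihood_gradient(h, cohort),
            rng=np.random.default_rng(2),
        )
        assert max(res.values()) < 1e-4

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        cfg = NetConfig(bandwidth=8, channels1=3, channels2=4, seed=5)
        model = RiskModel(cfg)
        coeffs = self._coeffs(rng, 3, 8)
        h0 = model.forward(coeffs)
        path = tmp_path / "model.h5"
        model.save(path)
        back = RiskModel.load(path)
        np.testing.assert_allclose(back.forward(coeffs), h0, atol=1e-7)

    def test_channel_mismatch_raises(self):
        cfg = NetConfig(bandwidth=8, channels1=3, channels2=4, seed=0)
        model = RiskModel(cfg)
        from sphsurv.spherical_mapping import SphericalMap

        bad = SphericalMap(
            grid=SphericalGrid(8),
            channels=["egi", "intensity"],
            values=np.zeros((2, 16, 16)),
        )
        with pytest.raises(ValueError):
            model.input_coeffs([bad])

    def test_dense_width_is_fixed_at_40(self):
        with pytest.raises(ValueError):
            NetConfig(bandwidth=8, dense_width=32).validate()
        assert RiskModel(NetConfig(bandwidth=8, seed=0)).params["dense_w"].shape[0] == 40
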