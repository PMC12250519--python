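"""SimAM / PSA attention operators and their combination topologies."""

import numpy as np
import pytest

from octseg.nn import (AttentionConfig, CombinedAttention, PSA, SimAM,
                       psa_param_count)
from octseg.nn.autograd import Tensor


def simam_oracle(x: np.ndarray, lam: float) -> np.ndarray:
    """Independent scalar-loop evaluation of the energy-attention formula."""
    c, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for ci in range(c):
        vals = [float(x[ci, i, j]) for i in range(h) for j in range(w)]
        mu = sum(vals) / len(vals)
        var = sum((v - mu) ** 2 for v in vals) / len(vals)
        for i in range(h):
            for j in range(w):
                d2 = (float(x[ci, i, j]) - mu) ** 2
                a = (d2 + 2 * var + 2 * lam) / (4 * (var + lam))
                out[ci, i, j] = x[ci, i, j] / (1 + np.exp(-a))
    return out


class TestSimAM:
    def test_matches_elementwise_oracle(self, rng):
        x = rng.standard_normal((2, 4, 4)).astype(np.float32)
        got = SimAM(1e-4)(Tensor(x[None])).data[0]
        assert np.allclose(got, simam_oracle(x, 1e-4), atol=1e-6)

    def test_constant_channel_uniform_scaling(self):
        x = np.full((1, 1, 3, 3), 0.7, np.float32)
        out = SimAM(1e-4)(Tensor(x)).data
        assert np.allclose(out, out.flat[0])  # spatially uniform

    def test_zero_learnable_parameters(self):
        assert SimAM(1e-4).num_parameters() == 0

    def test_weights_strictly_in_unit_interval(self, rng):
        x = rng.standard_normal((1, 3, 8, 8)).astype(np.float32) * 10
        xt = Tensor(x)
        w = SimAM(1e-4)(xt).data / np.where(x == 0, 1, x)
        w = w[x != 0]
        assert (w > 0).all() and (w < 1).all()

    def test_spatial_permutation_equivariance(self, rng):
        x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        sim = SimAM(1e-3)
        perm = rng.permutation(16)
        xp = x.reshape(1, 2, -1)[:, :, perm].reshape(1, 2, 4, 4)
        out = sim(Tensor(x)).data.reshape(1, 2, -1)[:, :, perm]
        out_p = sim(Tensor(xp)).data.reshape(1, 2, -1)
        assert np.allclose(out, out_p, atol=1e-6)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            SimAM(0.0)
        with pytest.raises(ValueError):
            AttentionConfig(simam_lambda=-1.0)


class TestPSA:
    @pytest.mark.parametrize("c", [16, 32, 64])
    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_shape_preserved(self, rng, c, s):
        cfg = AttentionConfig(mode="psa", psa_branches=s)
        psa = PSA(c, cfg, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, c, 8, 8)).astype(np.float32))
        assert psa(x).shape == (2, c, 8, 8)

    @pytest.mark.parametrize("c,s", [(16, 1), (16, 4), (64, 4), (32, 2)])
    def test_branch_softmax_sums_to_one(self, rng, c, s):
        cfg = AttentionConfig(mode="psa", psa_branches=s)
        psa = PSA(c, cfg, np.random.default_rng(1))
        x = Tensor(rng.standard_normal((3, c, 6, 6)).astype(np.float32))
        att = psa.branch_softmax(x)
        assert att.shape == (3, s, c // s)
        assert (att >= 0).all()
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("c", [16, 32, 64])
    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_param_count_closed_form(self, c, s):
        cfg = AttentionConfig(mode="psa", psa_branches=s)
        psa = PSA(c, cfg, np.random.default_rng(2))
        assert psa.num_parameters() == psa_param_count(c, cfg)

    def test_single_branch_softmax_is_identity_weight(self, rng):
        cfg = AttentionConfig(mode="psa", psa_branches=1)
        psa = PSA(8, cfg, np.random.default_rng(3))
        x = Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32))
        assert np.allclose(psa.branch_softmax(x), 1.0)
        # output equals the single conv branch (weight identically 1)
        feat = psa.convs[0](x[:, 0:8]).data
        assert np.allclose(psa(x).data, feat, atol=1e-6)

    def test_channel_split_bookkeeping(self):
        cfg = AttentionConfig(mode="psa", psa_branches=4)
        psa = PSA(64, cfg, np.random.default_rng(4))
        assert psa.branch_ch == 16
        x = Tensor(np.zeros((1, 64, 4, 4), np.float32))
        assert psa(x).shape[1] == 64

    def test_indivisible_channels_rejected(self):
        cfg = AttentionConfig(mode="psa", psa_branches=4)
        with pytest.raises(ValueError, match="C=10.*S=4"):
            PSA(10, cfg, np.random.default_rng(0))


class TestCombined:
    def _x(self, rng, c=16):
        return Tensor(rng.standard_normal((2, c, 8, 8)).astype(np.float32))

    def test_tandem_is_composition(self, rng):
        cfg = AttentionConfig(mode="tandem")
        blk = CombinedAttention(16, cfg, np.random.default_rng(5))
        x = self._x(rng)
        expected = blk.psa(blk.simam(x)).data
        assert np.array_equal(blk(x).data, expected)

    def test_parallel_zero_input_gives_zero(self):
        for fusion in ("sum", "mean"):
            cfg = AttentionConfig(mode="parallel", parallel_fusion=fusion)
            blk = CombinedAttention(16, cfg, np.random.default_rng(6))
            x = Tensor(np.zeros((1, 16, 4, 4), np.float32))
            # both operands are elementwise scalings of 0 up to conv bias;
            # zero the PSA conv biases to make the branch exactly linear
            for conv in blk.psa.convs:
                conv.bias.data[:] = 0.0
            assert np.allclose(blk(x).data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("mode", ["tandem", "parallel", "nested"])
    @pytest.mark.parametrize("c", [16, 32])
    def test_all_modes_shape_preserving(self, rng, mode, c):
        cfg = AttentionConfig(mode=mode)
        blk = CombinedAttention(c, cfg, np.random.default_rng(7))
        x = self._x(rng, c)
        assert blk(x).shape == x.shape

    def test_nested_large_lambda_limit(self, rng):
        """With S=1 and lambda -> inf the inner SimAM becomes a uniform
        sigmoid(1/2) scaling, so nested converges to a rescaled plain PSA."""
        x = self._x(rng, c=8)
        plain = PSA(8, AttentionConfig(mode="psa", psa_branches=1),
                    np.random.default_rng(8))
        nested = PSA(8, AttentionConfig(mode="nested", psa_branches=1,
                                        simam_lambda=1e8),
                     np.random.default_rng(8), nested_simam=True)
        scale = 1.0 / (1.0 + np.exp(-0.5))
        got = nested(x).data
        want = plain(x).data * scale
        denom = np.abs(want).max()
        assert np.abs(got - want).max() / denom < 1e-3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(mode="bogus")
        with pytest.raises(ValueError):
            CombinedAttention(16, AttentionConfig(mode="simam"),
                              np.random.default_rng(0))
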