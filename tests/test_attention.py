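"""CSAM: pooled descriptors, channel/spatial attention, residual aggregation."""

import numpy as np
import pytest

from mammofusion.attention import (
    CSAM,
    CSAMParams,
    channel_attention,
    csam_forward,
    pool_descriptors,
    spatial_attention,
)
from mammofusion.nn import Tensor, no_grad


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# --------------------------------------------------------------- descriptors
class TestPoolDescriptors:
    def test_constant_field_gives_constant_descriptors(self):
        F = np.full((3, 4, 5), 2.5)
        d = pool_descriptors(F)
        for arr in (d.channel_avg, d.channel_max, d.spatial_avg, d.spatial_max):
            np.testing.assert_allclose(arr, 2.5)

    def test_single_spike_channel(self):
        F = np.zeros((2, 4, 4))
        F[0, 1, 2] = 1.0
        d = pool_descriptors(F)
        assert d.channel_avg[0] == pytest.approx(1 / 16)
        assert d.channel_max[0] == 1.0
        assert d.channel_avg[1] == d.channel_max[1] == 0.0

    def test_matches_bruteforce_loops(self, rng):
        F = rng.normal(size=(3, 4, 4))
        d = pool_descriptors(F)
        for c in range(3):
            vals = [F[c, i, j] for i in range(4) for j in range(4)]
            assert d.channel_avg[c] == pytest.approx(sum(vals) / 16)
            assert d.channel_max[c] == pytest.approx(max(vals))
        for i in range(4):
            for j in range(4):
                col = [F[c, i, j] for c in range(3)]
                assert d.spatial_avg[i, j] == pytest.approx(sum(col) / 3)
                assert d.spatial_max[i, j] == pytest.approx(max(col))

    def test_max_dominates_avg_invariant(self, rng):
        d = pool_descriptors(rng.normal(size=(5, 6, 7)))
        assert np.all(d.channel_max >= d.channel_avg)
        assert np.all(d.spatial_max >= d.spatial_avg)

    def test_nonfinite_rejected(self):
        F = np.zeros((1, 2, 2))
        F[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            pool_descriptors(F)


# ---------------------------------------------------------- channel attention
class TestChannelAttention:
    def test_zero_parameters_give_half_everywhere(self, rng):
        F = rng.normal(size=(8, 3, 3))
        mc = channel_attention(F, CSAMParams.zeros(8, r=4))
        np.testing.assert_allclose(mc, 0.5)

    def test_identity_weights_hand_value(self):
        # C=2, r=1, identity MLP, channel means (1, 0) = maxima:
        # gate = sigmoid(mlp(avg) + mlp(max)) = sigmoid((2, 0))
        F = np.zeros((2, 2, 2))
        F[0] = 1.0
        p = CSAMParams.zeros(2, r=1)
        p.W0 = np.eye(2)
        p.W1 = np.eye(2)
        mc = channel_attention(F, p)
        np.testing.assert_allclose(mc, sigmoid([2.0, 0.0]), atol=1e-4)
        assert mc[0] == pytest.approx(0.8808, abs=1e-4)

    def test_matches_straightline_oracle(self, rng):
        F = rng.normal(size=(8, 5, 6))
        p = CSAMParams.random(8, r=2, rng=rng)
        p.b0 = rng.normal(size=4)
        p.b1 = rng.normal(size=8)
        avg, mx = F.mean(axis=(1, 2)), F.max(axis=(1, 2))

        def mlp(v):
            return p.W1 @ np.maximum(p.W0 @ v + p.b0, 0) + p.b1

        np.testing.assert_allclose(channel_attention(F, p),
                                   sigmoid(mlp(avg) + mlp(mx)), rtol=1e-10)

    def test_constant_input_reduces_to_twice_mlp(self, rng):
        # avg == max, so the shared-MLP-then-sum form gives sigmoid(2*MLP(v))
        F = np.full((4, 3, 3), 1.7)
        p = CSAMParams.random(4, r=2, rng=rng)
        v = F.mean(axis=(1, 2))
        mlp_v = p.W1 @ np.maximum(p.W0 @ v + p.b0, 0) + p.b1
        np.testing.assert_allclose(channel_attention(F, p), sigmoid(2 * mlp_v),
                                   rtol=1e-10)

    def test_monotone_in_output_bias(self, rng):
        F = rng.normal(size=(4, 3, 3))
        p = CSAMParams.random(4, r=2, rng=rng)
        base = channel_attention(F, p)
        p.b1 = p.b1.copy()
        p.b1[2] += 1.0
        bumped = channel_attention(F, p)
        assert bumped[2] > base[2]
        np.testing.assert_allclose(np.delete(bumped, 2), np.delete(base, 2))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_attention(rng.normal(size=(6, 3, 3)), CSAMParams.zeros(8, r=4))


# ---------------------------------------------------------- spatial attention
class TestSpatialAttention:
    def test_zero_parameters_give_half_everywhere(self, rng):
        ms = spatial_attention(rng.normal(size=(3, 5, 7)), CSAMParams.zeros(3, r=1))
        np.testing.assert_allclose(ms, 0.5)

    def test_constant_field_uniform_interior(self, rng):
        F = np.full((2, 12, 12), 0.8)
        p = CSAMParams.random(2, r=1, rng=rng)
        ms = spatial_attention(F, p)
        interior = ms[3:-3, 3:-3]  # away from zero-padding effects
        np.testing.assert_allclose(interior, interior[0, 0], rtol=1e-10)

    def test_matches_naive_convolution_oracle(self, rng):
        F = rng.normal(size=(4, 9, 9))
        p = CSAMParams.random(4, r=2, rng=rng)
        avg, mx = F.mean(axis=0), F.max(axis=0)
        red = (p.spatial_reduce_w[0, 0, 0, 0] * avg
               + p.spatial_reduce_w[0, 1, 0, 0] * mx + p.spatial_reduce_b[0])

        def conv_same(img, kernel):
            kh, kw = kernel.shape
            out = np.zeros_like(img)
            ph, pw = kh // 2, kw // 2
            padded = np.pad(img, ((ph, ph), (pw, pw)))
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    out[i, j] = (padded[i:i + kh, j:j + kw] * kernel).sum()
            return out

        expected = sigmoid(
            conv_same(conv_same(red, p.spatial_k7x1) + p.spatial_k7x1_b[0],
                      p.spatial_k1x7) + p.spatial_k1x7_b[0])
        np.testing.assert_allclose(spatial_attention(F, p), expected, rtol=1e-8)


# ----------------------------------------------------------------- aggregate
class TestCsamForward:
    def test_zero_parameters_triple_input(self, rng):
        F = rng.normal(size=(8, 6, 5))
        np.testing.assert_allclose(csam_forward(F, CSAMParams.zeros(8, r=4)), 3 * F)

    def test_zero_input_maps_to_zero(self, rng):
        F = np.zeros((4, 3, 3))
        p = CSAMParams.random(4, r=2, rng=rng)
        np.testing.assert_allclose(csam_forward(F, p), 0.0)

    def test_composition_of_branch_oracles(self, rng):
        F = rng.normal(size=(8, 4, 6))
        p = CSAMParams.random(8, r=4, rng=rng)
        mc = channel_attention(F, p)[:, None, None]
        ms = spatial_attention(F, p)[None]
        np.testing.assert_allclose(csam_forward(F, p),
                                   (F + F * mc) + (F + F * ms), rtol=1e-12)

    def test_algebraic_identity_two_f_plus_gated(self, rng):
        # F' = 2F + F * (M_C broadcast-plus M_S), for any parameters
        F = rng.normal(size=(4, 5, 5))
        p = CSAMParams.random(4, r=2, rng=rng)
        gate = channel_attention(F, p)[:, None, None] + spatial_attention(F, p)[None]
        np.testing.assert_allclose(csam_forward(F, p), 2 * F + F * gate, rtol=1e-12)

    def test_output_shape_and_attention_open_interval(self, rng):
        for shape in [(4, 1, 1), (8, 3, 9), (16, 2, 2)]:
            F = rng.normal(size=shape)
            p = CSAMParams.random(shape[0], r=2, rng=rng)
            assert csam_forward(F, p).shape == shape
            mc = channel_attention(F, p)
            ms = spatial_attention(F, p)
            assert np.all((mc > 0) & (mc < 1))
            assert np.all((ms > 0) & (ms < 1))

    def test_module_agrees_with_functional_route(self, rng):
        F = rng.normal(size=(8, 6, 6))
        p = CSAMParams.random(8, r=4, rng=rng)
        module = CSAM(8, r=4).load_csam_params(p)
        with no_grad():
            out = module(Tensor(F[None])).data[0]
        np.testing.assert_allclose(out, csam_forward(F, p), rtol=1e-10)
        roundtrip = module.get_csam_params()
        np.testing.assert_allclose(roundtrip.W0, p.W0)

    def test_reduction_ratio_divisibility_enforced(self):
        with pytest.raises(ValueError):
            CSAMParams.zeros(6, r=4)
        with pytest.raises(ValueError):
            CSAM(6, r=4)
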