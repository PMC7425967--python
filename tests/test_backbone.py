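"""Multi-scale dense blocks, transitions, and the full backbone."""

import numpy as np
import pytest

from mammofusion.backbone import (
    BackboneSpec,
    DenseBlock,
    DenseBlockSpec,
    MultiScaleAttentionDenseNet,
    MultiScaleBlock,
    Transition,
    backbone_forward,
    count_depth,
    dense_block_forward,
    multiscale_block_forward,
    transition_forward,
)


# ----------------------------------------------------------- building block
class TestMultiScaleBlock:
    def test_identity_kernels_give_cumulative_subsets(self, rng):
        # with impulse kernels, no BN, zero CSAM: the hierarchical residual
        # y_i = K_i(X_i + y_{i-1}) unrolls to cumulative sums of the subsets,
        # and zero-parameter CSAM contributes an exact factor 3
        k = 8
        block = MultiScaleBlock(k, k, reduction_ratio=4, batch_norm=False)
        block.set_identity_kernels()
        block.csam.zero_()
        F = rng.random((k, 5, 5))  # non-negative so ReLU is the identity
        out = multiscale_block_forward(F, block)
        X = [F[2 * i:2 * i + 2] for i in range(4)]
        cumulative = np.concatenate([X[0], X[0] + X[1], X[0] + X[1] + X[2],
                                     X[0] + X[1] + X[2] + X[3]])
        # independent loop oracle for the same recursion
        y, ys = None, []
        for i in range(4):
            y = X[i] if y is None else X[i] + y
            ys.append(y)
        np.testing.assert_allclose(out, 3 * cumulative, rtol=1e-12)
        np.testing.assert_allclose(out, 3 * np.concatenate(ys), rtol=1e-12)

    def test_zero_input_propagates_to_zero(self):
        block = MultiScaleBlock(6, 8, reduction_ratio=4, batch_norm=False)
        out = multiscale_block_forward(np.zeros((6, 4, 4)), block)
        np.testing.assert_allclose(out, 0.0)

    def test_output_channels_equal_growth_rate(self, rng):
        for c_in, k in [(6, 8), (16, 8), (10, 12)]:
            block = MultiScaleBlock(c_in, k, reduction_ratio=4)
            out = multiscale_block_forward(rng.random((c_in, 6, 6)), block)
            assert out.shape == (k, 6, 6)

    def test_growth_rate_divisibility_enforced(self):
        with pytest.raises(ValueError):
            MultiScaleBlock(8, 10, reduction_ratio=2)

    def test_factorised_pair_parameter_economy(self):
        # a 3x1 + 1x3 pair over g channels costs 6g^2 weights vs 9g^2 full 3x3
        block = MultiScaleBlock(8, 8, reduction_ratio=4)
        g = block.g
        for unit in block.k_units:
            pair = unit.conv_3x1.weight.size + unit.conv_1x3.weight.size
            assert pair == 6 * g * g
            assert 9 * g * g - pair == 3 * g * g

    def test_receptive_field_grows_along_subset_path(self):
        # impulse response: y4's path (three K applications) spreads wider
        # than y2's (one application)
        k = 8
        block = MultiScaleBlock(k, k, reduction_ratio=4, batch_norm=False)
        block.set_identity_kernels()
        block.csam.zero_()
        for unit in block.k_units:  # small blur so support actually spreads
            unit.conv_3x1.weight.data[:, :, :, 0] = 0.0
            for c in range(block.g):
                unit.conv_3x1.weight.data[c, c, :, 0] = 1.0
            unit.conv_1x3.weight.data[:, :, 0, :] = 0.0
            for c in range(block.g):
                unit.conv_1x3.weight.data[c, c, 0, :] = 1.0
        F = np.zeros((k, 15, 15))
        F[:, 7, 7] = 1.0  # centred impulse in every subset
        out = multiscale_block_forward(F, block)
        g = block.g

        def support_width(channel_slice):
            nz = np.nonzero(out[channel_slice].sum(axis=0))[0]
            return nz.max() - nz.min() + 1

        w2 = support_width(slice(g, 2 * g))       # y2: one K
        w4 = support_width(slice(3 * g, 4 * g))   # y4: three K
        assert w4 > w2


# -------------------------------------------------------------- dense block
class TestDenseBlock:
    def test_channel_arithmetic(self, rng):
        block = DenseBlock(64, DenseBlockSpec(6, 32), reduction_ratio=16)
        out = dense_block_forward(rng.random((64, 4, 4)), block)
        assert out.shape[0] == 64 + 6 * 32 == 256

    def test_single_layer_reduces_to_block_plus_concat(self, rng):
        F = rng.random((8, 5, 5))
        dense = DenseBlock(8, DenseBlockSpec(1, 8), reduction_ratio=4)
        expected = np.concatenate(
            [F, multiscale_block_forward(F, dense.layers[0])])
        np.testing.assert_allclose(dense_block_forward(F, dense), expected,
                                   rtol=1e-12)

    @pytest.mark.parametrize("L", [1, 3, 6])
    def test_connection_count_is_triangular(self, rng, L):
        dense = DenseBlock(8, DenseBlockSpec(L, 8), reduction_ratio=4)
        dense_block_forward(rng.random((8, 4, 4)), dense)
        assert dense.connection_count == L * (L + 1) // 2

    def test_spatial_size_preserved(self, rng):
        dense = DenseBlock(8, DenseBlockSpec(2, 8), reduction_ratio=4)
        out = dense_block_forward(rng.random((8, 6, 10)), dense)
        assert out.shape[1:] == (6, 10)


# -------------------------------------------------------------- transitions
class TestTransition:
    def test_halves_channels_and_space(self, rng):
        out = transition_forward(rng.random((256, 16, 16)))
        assert out.shape == (128, 8, 8)

    def test_constant_map_pools_to_same_constant(self):
        tr = Transition(4, batch_norm=False)
        # bypass the conv by making it an identity-summing projection
        tr.conv.weight.data = np.zeros_like(tr.conv.weight.data)
        tr.conv.weight.data[0, 0, 0, 0] = 1.0
        tr.conv.weight.data[1, 1, 0, 0] = 1.0
        out = transition_forward(np.full((4, 6, 6), 2.0), tr)
        np.testing.assert_allclose(out[:2], 2.0)

    def test_pool_matches_strided_window_mean_oracle(self, rng):
        F = rng.random((2, 6, 6))
        tr = Transition(2, batch_norm=False)
        out = transition_forward(F, tr)
        # reconstruct: conv then naive 2x2 window means
        w = tr.conv.weight.data[:, :, 0, 0]
        conved = np.einsum("oc,chw->ohw", w, np.maximum(F, 0)) \
            + tr.conv.bias.data[:, None, None]
        expected = np.zeros((1, 3, 3))
        for i in range(3):
            for j in range(3):
                expected[0, i, j] = conved[0, 2*i:2*i+2, 2*j:2*j+2].mean()
        np.testing.assert_allclose(out[0], expected[0], rtol=1e-10)

    def test_odd_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            Transition(5)
        with pytest.raises(ValueError):
            transition_forward(rng.random((4, 5, 6)), Transition(4))


# ------------------------------------------------------------ full backbone
class TestBackbone:
    def test_canonical_accounting_without_forward(self):
        spec = BackboneSpec()
        assert count_depth(spec) == 186
        assert spec.table_trace() == (256, 128, 128, 64, 64, 32, 32, 16, 16, 8, 1)
        assert spec.channel_trace() == [64, 256, 128, 512, 256, 1024, 512,
                                        1536, 768, 1280]

    def test_depth_convention_closed_form(self):
        small = BackboneSpec(input_size=64, stem_channels=8, block_sizes=(1,),
                             growth_rate=8, reduction_ratio=4)
        assert count_depth(small) == 1 + 2 + 0 + 1
        for sizes in [(2, 2), (3, 1, 2)]:
            spec = BackboneSpec(input_size=256, stem_channels=8,
                                block_sizes=sizes, growth_rate=8,
                                reduction_ratio=4)
            assert count_depth(spec) == 2 * sum(sizes) + (len(sizes) - 1) + 2

    def test_small_forward_stage_trace(self, small_spec, rng):
        net = MultiScaleAttentionDenseNet(small_spec, seed=0)
        vec, trace = backbone_forward(rng.random((1, 64, 64)), net)
        names = [n for n, _ in trace]
        assert names == ["stem_conv", "stem_pool", "dense_block_1",
                         "transition_1", "dense_block_2", "global_pool"]
        sizes = {n: s for n, s in trace}
        assert sizes["stem_conv"][2:] == (32, 32)
        assert sizes["stem_pool"][2:] == (16, 16)
        assert sizes["transition_1"][2:] == (8, 8)
        assert vec.shape == (small_spec.feature_dim,)

    def test_forward_is_deterministic(self, small_spec, rng):
        net = MultiScaleAttentionDenseNet(small_spec, seed=3)
        img = rng.random((1, 64, 64))
        v1, _ = backbone_forward(img, net)
        v2, _ = backbone_forward(img, net)
        np.testing.assert_array_equal(v1, v2)

    def test_wrong_input_size_rejected(self, small_spec, rng):
        net = MultiScaleAttentionDenseNet(small_spec, seed=0)
        with pytest.raises(ValueError, match="64x64"):
            backbone_forward(rng.random((1, 32, 32)), net)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BackboneSpec(growth_rate=30)  # not divisible by 4
        with pytest.raises(ValueError):
            BackboneSpec(growth_rate=32, reduction_ratio=24)
        with pytest.raises(ValueError):
            BackboneSpec(input_size=100)  # not divisible by downsampling
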