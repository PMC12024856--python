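"""Building blocks: separable convolutions, recursion, GRN and the trunk
block families, with closed-form parameter-count oracles."""

import numpy as np
import pytest

from octaseg import (
    BlockConfig,
    DepthwiseSeparableConv,
    GRN,
    ImprovedConvNeXtV2Block,
    OriginalConvNeXtV2Block,
    RecursiveConv,
    ResidualBlock,
    Tensor,
    count_parameters,
    recursive_apply,
)
from octaseg.blocks import effective_receptive_field, grn, millions_2dp
from octaseg import nn


def ds_param_formula(cin, cout, k):
    """Closed-form count for a biased separable conv: depthwise + pointwise."""
    return (cin * k * k + cin) + (cin * cout + cout)


class TestDepthwiseSeparableConv:
    def test_param_count_example(self):
        # 32 -> 32 with a 7x7 kernel: 32*49+32 depthwise, 32*32+32 pointwise
        conv = DepthwiseSeparableConv(32, 32, 7)
        assert conv.num_parameters() == 2656

    def test_param_count_formula_randomized(self, rng):
        for _ in range(20):
            cin = int(rng.integers(1, 40))
            cout = int(rng.integers(1, 40))
            k = int(rng.choice([1, 3, 5, 7]))
            conv = DepthwiseSeparableConv(cin, cout, k)
            assert conv.num_parameters() == ds_param_formula(cin, cout, k)

    def test_dilation_preserves_shape(self, rng):
        conv = DepthwiseSeparableConv(4, 4, 3, dilation=3)
        x = Tensor(rng.standard_normal((1, 4, 13, 17)).astype(np.float32))
        assert conv(x).shape == (1, 4, 13, 17)
        assert effective_receptive_field(3, 3) == 7

    def test_zero_input_bias_free_gives_zero(self):
        conv = DepthwiseSeparableConv(3, 5, 3, bias=False)
        out = conv(Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32)))
        assert np.all(out.data == 0.0)

    def test_channel_mismatch_raises(self, rng):
        conv = DepthwiseSeparableConv(3, 5, 3)
        with pytest.raises(ValueError, match="channel"):
            conv(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            DepthwiseSeparableConv(3, 3, 4)


class TestRecursion:
    def test_r1_is_single_application(self, rng):
        conv = nn.Conv2d(3, 3, 3, rng=rng)
        x = Tensor(rng.standard_normal((1, 3, 9, 9)).astype(np.float32))
        np.testing.assert_array_equal(recursive_apply(conv, x, 1).data,
                                      conv(x).data)

    def test_identity_kernel_doubles_constant(self):
        # 1x1 identity kernel, no bias: y1 = c, y2 = conv(c + c) = 2c
        conv = nn.Conv2d(1, 1, 1, bias=False)
        conv.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
        c = 0.75
        x = Tensor(np.full((1, 1, 4, 4), c, dtype=np.float32))
        out = recursive_apply(conv, x, 2)
        np.testing.assert_allclose(out.data, 2 * c, rtol=1e-6)

    def test_invalid_depth_rejected(self, rng):
        conv = nn.Conv2d(2, 2, 3, rng=rng)
        x = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="recursion"):
            recursive_apply(conv, x, 0)

    def test_channel_changing_operator_rejected(self, rng):
        conv = nn.Conv2d(2, 5, 3, rng=rng)
        x = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="preserve"):
            recursive_apply(conv, x, 2)

    def test_wrapper_shares_weights_across_depth(self, rng):
        base = nn.Conv2d(3, 3, 3, rng=rng)
        assert RecursiveConv(base, 1).num_parameters() == \
            RecursiveConv(base, 2).num_parameters() == base.num_parameters()

    def test_wrapper_handles_channel_change(self, rng):
        wrapped = RecursiveConv(nn.Conv2d(3, 7, 3, rng=rng), R=2)
        x = Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        assert wrapped(x).shape == (1, 7, 6, 6)


class TestGRN:
    def test_identity_at_zero_init(self, rng):
        layer = GRN(5)
        x = Tensor(rng.standard_normal((2, 5, 6, 6)).astype(np.float32))
        assert np.abs(layer(x).data - x.data).max() == 0.0

    def test_zero_input_maps_to_zero(self):
        layer = GRN(4)
        layer.weight.data = np.full((1, 4, 1, 1), 2.0, dtype=np.float32)
        out = layer(Tensor(np.zeros((1, 4, 3, 3), dtype=np.float32)))
        assert np.all(out.data == 0.0)

    def test_single_channel_norm_ratio_is_one(self, rng):
        # with one channel, N = G / mean(G) = 1, so out = gamma*x + beta + x
        x = rng.standard_normal((1, 1, 5, 5)).astype(np.float32)
        gamma = np.array([0.7], dtype=np.float32)
        beta = np.array([-0.2], dtype=np.float32)
        out = grn(Tensor(x), Tensor(gamma), Tensor(beta))
        np.testing.assert_allclose(out.data, gamma * x + beta + x,
                                   rtol=1e-4, atol=1e-5)

    def test_length_mismatch_rejected(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="length"):
            grn(x, Tensor(np.zeros(2)), Tensor(np.zeros(3)))

    def test_adds_two_parameters_per_channel(self):
        assert GRN(32).num_parameters() == 64


@pytest.mark.parametrize("block_cls,kind", [
    (ImprovedConvNeXtV2Block, "conv3x3"),
    (OriginalConvNeXtV2Block, "conv1x1"),
    (ResidualBlock, "conv3x3"),
])
class TestTrunkBlocks:
    def test_shape_preserved_at_random_sizes(self, block_cls, kind, rng):
        cfg = BlockConfig(channels=8, expansion_width=12, pointwise_kind=kind)
        block = block_cls(cfg, rng=rng)
        for _ in range(4):
            h, w = rng.integers(16, 40, size=2)
            x = Tensor(rng.standard_normal((1, 8, h, w)).astype(np.float32))
            assert block(x).shape == (1, 8, h, w)

    def test_zero_input_zero_params_gives_zero(self, block_cls, kind, rng):
        # biases, GRN gain/bias and norm shifts all initialise to zero, so a
        # zero input must propagate to a zero output through the residual
        cfg = BlockConfig(channels=4, expansion_width=6, pointwise_kind=kind)
        block = block_cls(cfg, rng=rng)
        out = block(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
        assert np.all(out.data == 0.0)


class TestBlockParameterCounts:
    def test_recursion_depth_never_changes_count(self, rng):
        for r in (1, 2, 3):
            cfg = BlockConfig(channels=32, recursion_R=r, expansion_width=48)
            assert ImprovedConvNeXtV2Block(cfg, rng=rng).num_parameters() == \
                ImprovedConvNeXtV2Block(
                    BlockConfig(channels=32, recursion_R=1, expansion_width=48),
                    rng=rng).num_parameters()

    def test_recursion_changes_outputs_not_count(self, rng):
        cfg1 = BlockConfig(channels=8, recursion_R=1, expansion_width=12)
        cfg2 = BlockConfig(channels=8, recursion_R=2, expansion_width=12)
        b1 = ImprovedConvNeXtV2Block(cfg1, rng=np.random.default_rng(3))
        b2 = ImprovedConvNeXtV2Block(cfg2, rng=np.random.default_rng(3))
        x = Tensor(rng.standard_normal((1, 8, 12, 12)).astype(np.float32))
        assert b1.num_parameters() == b2.num_parameters()
        assert np.abs(b1(x).data - b2(x).data).max() > 1e-6

    def test_original_block_smaller_than_improved(self, rng):
        cfg = BlockConfig(channels=32, expansion_width=48)
        improved = ImprovedConvNeXtV2Block(cfg, rng=rng).num_parameters()
        original = OriginalConvNeXtV2Block(
            BlockConfig(channels=32, expansion_width=48,
                        pointwise_kind="conv1x1"), rng=rng).num_parameters()
        assert original < improved

    def test_residual_block_closed_form(self, rng):
        c = 16
        block = ResidualBlock(BlockConfig(channels=c), rng=rng)
        # two biased 3x3 convs plus two batch norms (weight + bias each)
        assert block.num_parameters() == 2 * (c * c * 9 + c) + 2 * (2 * c)

    def test_single_conv_count(self):
        assert nn.Conv2d(1, 32, 3).num_parameters() == 320


class TestParamReport:
    def test_round_half_up_at_the_margin(self):
        assert millions_2dp(115_000) == 0.12
        assert millions_2dp(114_999) == 0.11
        assert millions_2dp(189_360) == 0.19

    def test_total_is_sum_of_components(self, rng):
        block = ImprovedConvNeXtV2Block(
            BlockConfig(channels=8, expansion_width=12), rng=rng)
        report = count_parameters(block)
        assert report.total == sum(n for _, n in report.per_component)
        assert report.total == block.num_parameters()

    def test_serialises_to_text_and_json(self, rng):
        report = count_parameters(nn.Conv2d(1, 4, 3, rng=rng))
        assert "total" in report.to_text()
        assert '"total"' in report.to_json()
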