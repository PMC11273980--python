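"""Hybrid channel + spatial attention: gate algebra, traces, accounting."""

import numpy as np
import pytest

from tumornet import autodiff as ad
from tumornet.attention import (AttentionSpec, ChannelAttention, HybridAttention,
                                SpatialAttention, attention_param_count)
from tumornet.nn_math import sigmoid as ref_sigmoid

from test_conv_block import enumerate_parameters


class TestChannelAttention:
    def test_constant_channels_make_avg_equal_max(self, rng):
        att = ChannelAttention(AttentionSpec(4, 2), rng)
        x = np.zeros((1, 4, 5, 5), dtype=np.float32)
        for c in range(4):
            x[0, c] = c - 1.5
        from tumornet.attention import AttentionTrace

        trace = AttentionTrace()
        att(ad.Tensor(x), trace=trace)
        np.testing.assert_allclose(trace.Aavg, trace.Amax, atol=1e-6)

    def test_zero_weights_gate_is_half(self, rng, make_zeroed):
        att = make_zeroed(ChannelAttention(AttentionSpec(6, 2), rng))
        x = rng.standard_normal((2, 6, 4, 4)).astype(np.float32)
        from tumornet.attention import AttentionTrace

        trace = AttentionTrace()
        out = att(ad.Tensor(x), trace=trace)
        np.testing.assert_allclose(trace.S, 0.5, atol=1e-7)
        np.testing.assert_allclose(out.data, 1.5 * x, rtol=1e-5)

    def test_single_pixel_hand_oracle(self, rng):
        """C=2, H=W=1: every step collapses to scalar arithmetic."""
        spec = AttentionSpec(2, 2)  # Cr = 1
        att = ChannelAttention(spec, rng)
        x = np.array([[[[0.8]], [[-0.4]]]], dtype=np.float32)
        wr = att.reduce.weight.data.reshape(2).astype(float)   # (1,2,1,1)
        br = float(att.reduce.bias.data[0])
        ws = att.scale.weight.data.reshape(2, 2).astype(float)  # (C=2, 2Cr=2)
        bs = att.scale.bias.data.astype(float)
        eps = 1e-3
        fr = max((wr[0] * 0.8 + wr[1] * -0.4 + br) / np.sqrt(1 + eps), 0.0)
        # 1x1 image: average pool == max pool == fr
        s = ref_sigmoid(ws @ np.array([fr, fr]) + bs)
        expected = x[0, :, 0, 0] * (1 + s)
        out = att(ad.Tensor(x))
        np.testing.assert_allclose(out.data[0, :, 0, 0], expected, rtol=1e-5)

    def test_channel_mismatch_error(self, rng):
        att = ChannelAttention(AttentionSpec(4, 2), rng)
        with pytest.raises(ValueError, match="channel"):
            att(ad.Tensor(np.zeros((1, 3, 2, 2))))


class TestSpatialAttention:
    def test_zero_weights_residual_algebra(self, rng, make_zeroed):
        att = make_zeroed(SpatialAttention(5, rng))
        x = rng.standard_normal((2, 5, 6, 6)).astype(np.float32)
        out = att(ad.Tensor(x))
        np.testing.assert_allclose(out.data, 1.5 * x, rtol=1e-5)

    def test_single_pixel_center_tap_oracle(self, rng):
        """H=W=1: same padding reduces every conv to its center tap."""
        att = SpatialAttention(1, rng)
        x = np.array([[[[0.6]]]], dtype=np.float32)
        eps = 1e-3
        wc = float(att.condense.weight.data[0, 0, 0, 0])
        bc = float(att.condense.bias.data[0])
        fc = max((wc * 0.6 + bc) / np.sqrt(1 + eps), 0.0)
        c1 = float(att.conv3.weight.data[0, 0, 1, 1]) * fc + float(att.conv3.bias.data[0])
        c2 = float(att.conv5.weight.data[0, 0, 2, 2]) * fc + float(att.conv5.bias.data[0])
        a = ref_sigmoid(
            float(att.fuse.weight.data[0, 0, 1, 1]) * c1
            + float(att.fuse.weight.data[0, 1, 1, 1]) * c2
            + float(att.fuse.bias.data[0])
        )
        out = att(ad.Tensor(x))
        assert out.data.item() == pytest.approx(0.6 * (1 + a), rel=1e-4)

    @pytest.mark.parametrize("shape", [(1, 1, 1, 1), (2, 3, 7, 5), (1, 16, 14, 14)])
    def test_shape_contract(self, rng, shape):
        att = SpatialAttention(shape[1], rng)
        out = att(ad.Tensor(np.random.default_rng(1).standard_normal(shape)))
        assert out.data.shape == shape


class TestHybridAttention:
    @pytest.mark.parametrize("c,hw", [(1, 1), (2, 7), (16, 14), (256, 7)])
    def test_shape_preservation(self, rng, c, hw):
        att = HybridAttention(AttentionSpec(c, 2), rng)
        x = np.random.default_rng(2).standard_normal((1, c, hw, hw))
        out = att(ad.Tensor(x))
        assert out.data.shape == x.shape

    @pytest.mark.parametrize("c", [16, 256])
    def test_zero_weight_closed_form(self, rng, make_zeroed, c):
        """Both gates are exactly 0.5 -> output = 3.25 * input."""
        att = make_zeroed(HybridAttention(AttentionSpec(c, 2), rng))
        x = rng.standard_normal((2, c, 7, 7)).astype(np.float32)
        out = att(ad.Tensor(x))
        np.testing.assert_allclose(out.data, 3.25 * x, rtol=1e-5)

    def test_zero_input_with_zero_biases(self, rng, make_zeroed):
        att = make_zeroed(HybridAttention(AttentionSpec(8, 2), rng))
        out = att(ad.Tensor(np.zeros((1, 8, 5, 5))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_final_combination_is_plain_addition(self, rng):
        att = HybridAttention(AttentionSpec(8, 2), rng)
        x = rng.standard_normal((1, 8, 6, 6)).astype(np.float32)
        out, trace = att.forward_with_trace(ad.Tensor(x))
        # bitwise: the final step is the plain float addition x + F''
        np.testing.assert_array_equal(out.data, x + trace.Fdprime)

    def test_gate_ranges_strictly_open(self, rng):
        att = HybridAttention(AttentionSpec(16, 2), rng)
        x = rng.standard_normal((2, 16, 8, 8)).astype(np.float32)
        _, trace = att.forward_with_trace(ad.Tensor(x))
        for gate in (trace.S, trace.A):
            assert (gate > 0).all() and (gate < 1).all()

    def test_trace_shapes(self, rng):
        att = HybridAttention(AttentionSpec(16, 2), rng)
        x = rng.standard_normal((3, 16, 5, 5)).astype(np.float32)
        _, t = att.forward_with_trace(ad.Tensor(x))
        assert t.FR.shape == (3, 8, 5, 5)
        assert t.Aavg.shape == (3, 8) and t.Amax.shape == (3, 8)
        assert t.AF.shape == (3, 16, 1, 1)
        assert t.S.shape == (3, 16, 1, 1)
        assert t.Fprime.shape == (3, 16, 5, 5)
        assert t.FC.shape == (3, 1, 5, 5)
        assert t.C1.shape == t.C2.shape == t.A.shape == (3, 1, 5, 5)
        assert t.Fdprime.shape == (3, 16, 5, 5)

    def test_monotone_gating_via_injected_bias(self, rng, make_zeroed):
        """Saturating the channel gate drives F' to F (gate 0) or 2F (gate 1)."""
        att = make_zeroed(ChannelAttention(AttentionSpec(8, 2), rng))
        x = np.random.default_rng(3).standard_normal((1, 8, 4, 4)).astype(np.float32)
        att.scale.bias.data[...] = -30.0
        low = att(ad.Tensor(x))
        np.testing.assert_allclose(low.data, x, rtol=1e-5, atol=1e-7)
        att.scale.bias.data[...] = +30.0
        high = att(ad.Tensor(x))
        np.testing.assert_allclose(high.data, 2 * x, rtol=1e-5, atol=1e-7)


class TestParamCount:
    @pytest.mark.parametrize("c,expected", [(256, 99516), (16, 516), (2, 75)])
    def test_known_totals(self, c, expected):
        assert attention_param_count(AttentionSpec(c, 2)) == expected

    def test_even_channel_closed_form(self):
        for c in (2, 16, 32, 64, 128, 256):
            assert attention_param_count(AttentionSpec(c, 2)) == 1.5 * c * c + 4.5 * c + 60

    @pytest.mark.parametrize("c", [2, 16, 32, 64, 128, 256])
    def test_matches_enumeration_oracle(self, rng, c):
        spec = AttentionSpec(c, 2)
        att = HybridAttention(spec, rng)
        assert attention_param_count(spec) == enumerate_parameters(att)

    def test_reduced_channels_floor(self):
        assert AttentionSpec(5, 2).reduced_channels == 2
        assert AttentionSpec(1, 2).reduced_channels == 1
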