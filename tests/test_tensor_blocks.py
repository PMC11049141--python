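"""Contracts and oracles for the diagonal-axial mixing operators."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pisnet import nn
from pisnet.autodiff import Tensor
from pisnet.tensor_blocks import (DAMLPBlock, DAMLPConfig, ShiftSpec,
                                  TokenProjection, TokMLPBlock,
                                  compute_shift_geometry, da_mlp_forward,
                                  diagonal_shift, dwconv_encode, shift_height,
                                  token_project)


class TestShiftGeometry:
    @pytest.mark.parametrize("h,w,window,pad", [
        (16, 16, 4, 2),
        (8, 8, 2, 1),
        (5, 7, 1, 0),       # floor(sqrt(35)) = 5 -> window 1
        (256, 256, 64, 32),
    ])
    def test_adaptive_window(self, h, w, window, pad):
        spec = compute_shift_geometry(h, w)
        assert (spec.window_size, spec.pad) == (window, pad)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_shift_geometry(0, 16)

    def test_shift_spec_validates_pad(self):
        with pytest.raises(ValueError):
            ShiftSpec(window_size=4, pad=3)


class TestShiftHeight:
    def test_single_channel_down_shift(self):
        x = np.arange(9, dtype=float).reshape(1, 3, 3)  # rows a, b, c
        out = shift_height(x, [1])
        np.testing.assert_array_equal(out[0, 0], 0)
        np.testing.assert_array_equal(out[0, 1:], x[0, :2])

    def test_zero_offsets_identity(self, rng):
        x = rng.standard_normal((5, 6, 6))
        np.testing.assert_array_equal(shift_height(x, [0] * 5), x)

    def test_per_group_contract(self, rng):
        x = rng.standard_normal((3, 4, 4))
        out = shift_height(x, [-1, 0, 1])
        np.testing.assert_array_equal(out[0, :3], x[0, 1:])   # up
        np.testing.assert_array_equal(out[0, 3], 0)
        np.testing.assert_array_equal(out[1], x[1])           # unchanged
        np.testing.assert_array_equal(out[2, 1:], x[2, :3])   # down
        np.testing.assert_array_equal(out[2, 0], 0)

    def test_rejects_offset_as_large_as_height(self, rng):
        with pytest.raises(ValueError):
            shift_height(rng.standard_normal((1, 3, 3)), [3])


class TestDiagonalShift:
    def test_single_pixel_translations(self):
        x = np.zeros((1, 4, 4))
        x[0, 2, 1] = 1.0
        spec = ShiftSpec(window_size=2, pad=1)  # s = 1
        lr = diagonal_shift(x, spec, "lr")
        rl = diagonal_shift(x, spec, "rl")
        assert lr[0, 1, 2] == 1.0 and lr.sum() == 1.0
        assert rl[0, 1, 0] == 1.0 and rl.sum() == 1.0

    def test_zero_map_stays_zero(self):
        spec = ShiftSpec(window_size=2, pad=1)
        for d in ("lr", "rl"):
            assert diagonal_shift(np.zeros((2, 5, 5)), spec, d).sum() == 0

    def test_rejects_unknown_direction(self):
        with pytest.raises(ValueError):
            diagonal_shift(np.zeros((1, 4, 4)), ShiftSpec(2, 1), "up")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
    def test_matches_index_remap_oracle(self, seed, s):
        """out[c, r, k] == in[c, r+s, k-s] for 'lr' (brute-force remap)."""
        x = np.random.default_rng(seed).standard_normal((1, 8, 8))
        spec = ShiftSpec(window_size=2 * s, pad=s)
        out = diagonal_shift(x, spec, "lr")
        ref = np.zeros_like(x)
        for r in range(8):
            for k in range(8):
                if 0 <= r + s < 8 and 0 <= k - s < 8:
                    ref[0, r, k] = x[0, r + s, k - s]
        np.testing.assert_array_equal(out, ref)

    def test_interior_support_restored_by_inverse_translation(self, rng):
        """For support further than s from every border, each diagonal
        shift is inverted exactly by the opposite translation."""
        s = 2
        x = np.zeros((1, 12, 12))
        x[0, 4:8, 4:8] = rng.standard_normal((4, 4))
        spec = ShiftSpec(window_size=4, pad=2)
        lr = diagonal_shift(x, spec, "lr")
        np.testing.assert_allclose(np.roll(lr, (s, -s), axis=(1, 2)), x)
        rl = diagonal_shift(x, spec, "rl")
        np.testing.assert_allclose(np.roll(rl, (s, s), axis=(1, 2)), x)


class TestTokenProjection:
    def test_shape_contract(self, rng):
        x = rng.standard_normal((8, 16, 16))
        assert token_project(x, 32, stride=2).shape == (32, 8, 8)
        assert token_project(x, 32, stride=1).shape == (32, 16, 16)

    def test_linearity_with_zero_bias(self, rng):
        mod = TokenProjection(4, 8, stride=1, norm=False)
        mod.proj.bias.data[:] = 0
        zero = token_project(np.zeros((4, 8, 8)), 8, module=mod)
        np.testing.assert_array_equal(zero, 0)
        x = rng.standard_normal((4, 8, 8)).astype(np.float32)
        one = token_project(x, 8, module=mod)
        three = token_project(3 * x, 8, module=mod)
        np.testing.assert_allclose(three, 3 * one, rtol=1e-4, atol=1e-5)

    def test_rejects_indivisible_stride(self, rng):
        with pytest.raises(ValueError):
            token_project(rng.standard_normal((4, 7, 8)), 8, stride=2)


class TestDwconvEncode:
    def test_shape_and_depthwise_contract(self, rng):
        x = rng.standard_normal((6, 10, 10)).astype(np.float32)
        mod = nn.DepthwiseConv2d(6)
        base = dwconv_encode(x, mod)
        assert base.shape == x.shape
        xp = x.copy()
        xp[2] += 1.0   # perturb only channel 2
        diff = dwconv_encode(xp, mod) - base
        changed = [c for c in range(6) if np.abs(diff[c]).max() > 1e-7]
        assert changed == [2]

    def test_identity_kernel(self, rng):
        x = rng.standard_normal((3, 5, 5)).astype(np.float32)
        mod = nn.DepthwiseConv2d(3)
        mod.weight.data[:] = 0
        mod.weight.data[:, 0, 1, 1] = 1
        mod.bias.data[:] = 0
        np.testing.assert_allclose(dwconv_encode(x, mod), x, rtol=1e-6)


class TestDAMLPBlock:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            DAMLPConfig(32, 96)          # ratio 3 not allowed
        with pytest.raises(ValueError):
            DAMLPConfig(32, 32, dwconv_kernel=4)
        assert DAMLPConfig(32, 128).embed_dim == 128

    @pytest.mark.parametrize("c,h,w", [(32, 16, 16), (16, 8, 8), (8, 12, 20)])
    def test_shape_preservation(self, rng, c, h, w):
        x = rng.standard_normal((c, h, w)).astype(np.float32)
        assert da_mlp_forward(x).shape == (c, h, w)

    def test_residual_identity_with_zero_fusion(self, rng):
        block = DAMLPBlock(16)
        block.fc2.weight.data[:] = 0
        block.fc2.bias.data[:] = 0
        x = rng.standard_normal((16, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(da_mlp_forward(x, block), x)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            da_mlp_forward(rng.standard_normal((8, 8, 8)), DAMLPBlock(16))

    def test_parameter_count_matches_enumeration_oracle(self):
        """Weight-array sizes summed independently equal the block count."""
        c = 32
        block = DAMLPBlock(c)
        expected = (2 * c               # norm1
                    + c * c + c         # fc1
                    + c * 9 + c         # depthwise 3x3
                    + 4 * c             # norm2 on the 2C concat
                    + 2 * c * c + c)    # fc2 (2C -> C)
        enumerated = sum(p.data.size for _, p in block.named_parameters())
        assert enumerated == expected == 3 * c * c + 18 * c

    def test_branches_share_all_trainable_parameters(self, rng):
        """The two diagonal branches add no weights over the shared layers:
        the parameter set is identical to the same block with the branch
        order swapped, and evaluation order cannot change the count."""
        block = DAMLPBlock(12)
        names = sorted(n for n, _ in block.named_parameters())
        shared = {"norm1", "fc1", "dwconv", "norm2", "fc2"}
        assert {n.split(".")[0] for n in names} == shared

    def test_dual_branch_concat_order(self, rng):
        """Concat is [lr, rl]: zeroing the rl half of fc2 reproduces a
        single-branch lr computation."""
        block = DAMLPBlock(4)
        x = Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32))
        full = block(x).data
        block.fc2.weight.data[:, 4:] = 0   # kill the rl branch
        lr_only = block(x).data
        block.fc2.weight.data[:, :4] = 0   # now both
        none = block(x).data
        assert not np.allclose(full, lr_only)
        # with both halves zeroed only the bias + residual remain
        np.testing.assert_allclose(
            none, x.data + block.fc2.bias.data[None, :, None, None],
            rtol=1e-5, atol=1e-6)


class TestTokMLPBlock:
    def test_shape_and_residual(self, rng):
        block = TokMLPBlock(8)
        x = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        out = block(x)
        assert out.shape == x.shape
        block.fc2.weight.data[:] = 0
        block.fc2.bias.data[:] = 0
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_parameter_count(self):
        c = 24
        block = TokMLPBlock(c)
        assert sum(p.data.size for p in block.parameters()) == 2 * c * c + 14 * c
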