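"""Cross-masked convolution: mask construction, oracle equivalence, counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

from mlecg.nn import (Adam, CrossKernelMask, MaskedConv2d, build_mask,
                      conv2d_forward, effective_weight_count, masked_conv2d)


class TestBuildMask:
    @pytest.mark.parametrize("mode", ["full_cross", "strict_n4"])
    def test_3x3_has_five_ones(self, mode):
        m = build_mask((3, 3), mode)
        assert m.n_active == 5
        assert m.mask[1, 1] == 1

    def test_5x5_full_cross_has_nine(self):
        m = build_mask((5, 5), "full_cross")
        assert m.n_active == 9  # 2k - 1 along centre row + column
        assert np.all(m.mask[2, :] == 1) and np.all(m.mask[:, 2] == 1)

    def test_5x5_strict_n4_has_five(self):
        m = build_mask((5, 5), "strict_n4")
        assert m.n_active == 5

    def test_1x1_identity_support(self):
        assert build_mask((1, 1)).n_active == 1

    @pytest.mark.parametrize("size", [(2, 3), (3, 4), (4, 4)])
    def test_even_kernel_rejected(self, size):
        with pytest.raises(ValueError):
            build_mask(size)

    @given(k=st.sampled_from([1, 3, 5, 7, 9]))
    @settings(deadline=None, derandomize=True)
    def test_full_cross_count_law(self, k):
        assert build_mask((k, k), "full_cross").n_active == 2 * k - 1


class TestMaskedConv:
    def test_all_ones_cross_sums_to_five(self):
        x = np.ones((1, 1, 6, 6))
        w = np.ones((1, 1, 3, 3))
        mask = build_mask((3, 3), "full_cross")
        out = masked_conv2d(x, w, mask)
        assert out.shape == (1, 1, 4, 4)
        assert np.allclose(out, 5.0)  # 5-point cross of ones

    def test_table_geometry_12x1900(self):
        x = np.zeros((1, 1, 12, 1900))
        rng = np.random.default_rng(0)
        w = rng.normal(size=(32, 1, 5, 5))
        out = masked_conv2d(x, w, build_mask((5, 5)), stride=1, padding=2)
        assert out.shape == (1, 32, 12, 1900)

    def test_output_size_formula(self):
        x = np.zeros((2, 3, 11, 20))
        w = np.zeros((4, 3, 5, 5))
        out = conv2d_forward(x, w, None, stride=2, padding=1)
        assert out.shape == (2, 4, (11 + 2 - 5) // 2 + 1, (20 + 2 - 5) // 2 + 1)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            conv2d_forward(np.zeros((1, 2, 8, 8)), np.zeros((1, 3, 3, 3)), None)

    def test_matches_dense_oracle_100_trials(self):
        """masked conv == dense conv with weights*mask, 1e-6 relative."""
        rng = np.random.default_rng(42)
        mask = build_mask((3, 3), "full_cross")
        for _ in range(100):
            x = rng.normal(size=(1, 1, 8, 8))
            w = rng.normal(size=(1, 1, 3, 3))
            got = masked_conv2d(x, w, mask)
            want = correlate2d(x[0, 0], w[0, 0] * mask.mask, mode="valid")
            assert np.allclose(got[0, 0], want, rtol=1e-6)

    def test_dense_oracle_multichannel(self):
        rng = np.random.default_rng(3)
        mask = build_mask((5, 5), "full_cross")
        x = rng.normal(size=(2, 3, 10, 14))
        w = rng.normal(size=(4, 3, 5, 5))
        got = masked_conv2d(x, w, mask, padding=2)
        wm = w * mask.mask
        want = np.zeros_like(got)
        xp = np.pad(x, ((0, 0), (0, 0), (2, 2), (2, 2)))
        for n in range(2):
            for o in range(4):
                for c in range(3):
                    want[n, o] += correlate2d(xp[n, c], wm[o, c], mode="valid")
        assert np.allclose(got, want, rtol=1e-6, atol=1e-12)

    def test_linearity_in_input(self):
        rng = np.random.default_rng(9)
        mask = build_mask((3, 3))
        w = rng.normal(size=(2, 1, 3, 3))
        x, y = rng.normal(size=(2, 1, 1, 8, 8))
        f = lambda z: masked_conv2d(z, w, mask)
        assert np.allclose(f(2 * x + 3 * y), 2 * f(x) + 3 * f(y),
                           rtol=1e-9, atol=1e-12)

    def test_time_translation_equivariance(self):
        rng = np.random.default_rng(10)
        mask = build_mask((3, 3))
        w = rng.normal(size=(1, 1, 3, 3))
        x = rng.normal(size=(1, 1, 5, 40))
        shifted = np.roll(x, 7, axis=3)
        a = masked_conv2d(x, w, mask)
        b = masked_conv2d(shifted, w, mask)
        assert np.allclose(np.roll(a, 7, axis=3)[..., 10:30], b[..., 10:30],
                           rtol=1e-9)


class TestEffectiveWeightCount:
    def test_5x5_full_cross_1_to_32(self):
        assert effective_weight_count((5, 5), "full_cross", 1, 32) == 288
        assert 288 < 25 * 32  # strictly fewer than dense

    def test_3x3_single_channel(self):
        assert effective_weight_count((3, 3), "full_cross", 1, 1) == 5

    def test_1x1_equals_dense(self):
        assert effective_weight_count((1, 1), "full_cross", 3, 7) == 3 * 7


def test_masked_weights_stay_zero_through_adam_updates():
    """Off-cross weights remain exactly 0 after optimiser steps."""
    rng = np.random.default_rng(0)
    mask = build_mask((5, 5), "full_cross")
    conv = MaskedConv2d(1, 4, (5, 5), rng, mask=mask, padding=2)
    opt = Adam(conv.parameters(), lr=0.01)
    off = mask.mask == 0
    for _ in range(20):
        x = rng.normal(size=(2, 1, 12, 40))
        out = conv.forward(x)
        conv.backward(np.ones_like(out))
        opt.step()
        conv.remask()
        assert np.all(conv.params["w"][:, :, off] == 0.0)
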