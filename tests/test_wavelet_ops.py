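"""Haar analysis/synthesis correctness and the wavelet convolution block.

The independent oracle for the forward transform is PyWavelets' single-level
2-D Haar decomposition with periodization boundary handling (exact for even
sizes).  Sub-band naming differs between conventions: this package's
horizontal-detail band (differences along width) corresponds to pywt's cV,
and its vertical-detail band to pywt's cH; signs agree.
"""

import numpy as np
import pytest
import pywt

from waveseg import autograd as ag
from waveseg.autograd import Tensor
from waveseg.errors import ConfigurationError, ValidationError
from waveseg.wavelet_ops import (WaveletSubbands, WtConv, haar_dwt2d, haar_iwt2d,
                                 wtconv_forward)


class TestAnalysis:
    def test_constant_field_has_no_detail(self):
        s = haar_dwt2d(np.ones((1, 1, 4, 4)))
        np.testing.assert_allclose(s.ll.data, 2.0)
        for band in (s.lh, s.hl, s.hh):
            np.testing.assert_allclose(band.data, 0.0)

    def test_single_block_worked_example(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        s = haar_dwt2d(x)
        assert s.ll.data.item() == pytest.approx(5.0)
        assert s.lh.data.item() == pytest.approx(-1.0)
        assert s.hl.data.item() == pytest.approx(-2.0)
        assert s.hh.data.item() == pytest.approx(0.0)

    def test_matches_reference_filter_bank(self, rng):
        x = rng.standard_normal((2, 3, 16, 16))
        s = haar_dwt2d(x)
        for b in range(2):
            for c in range(3):
                cA, (cH, cV, cD) = pywt.dwt2(x[b, c], "haar", mode="periodization")
                np.testing.assert_allclose(s.ll.data[b, c], cA, atol=1e-6)
                np.testing.assert_allclose(s.lh.data[b, c], cV, atol=1e-6)
                np.testing.assert_allclose(s.hl.data[b, c], cH, atol=1e-6)
                np.testing.assert_allclose(s.hh.data[b, c], cD, atol=1e-6)

    def test_oracle_agreement_many_instances(self, rng):
        for _ in range(20):
            h = int(rng.integers(2, 13)) * 2
            w = int(rng.integers(2, 13)) * 2
            x = rng.standard_normal((1, 1, h, w))
            s = haar_dwt2d(x)
            cA, (cH, cV, cD) = pywt.dwt2(x[0, 0], "haar", mode="periodization")
            stacked = np.stack([s.ll.data[0, 0], s.lh.data[0, 0],
                                s.hl.data[0, 0], s.hh.data[0, 0]])
            ref = np.stack([cA, cV, cH, cD])
            assert np.abs(stacked - ref).max() < 1e-6

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 2, 8, 8))
        y = rng.standard_normal((1, 2, 8, 8))
        sa = haar_dwt2d(2.5 * x - 1.5 * y)
        sx, sy = haar_dwt2d(x), haar_dwt2d(y)
        for combined, bx, by in zip(
            (sa.ll, sa.lh, sa.hl, sa.hh), (sx.ll, sx.lh, sx.hl, sx.hh),
            (sy.ll, sy.lh, sy.hl, sy.hh),
        ):
            np.testing.assert_allclose(
                combined.data, 2.5 * bx.data - 1.5 * by.data, atol=1e-10
            )

    def test_parseval_energy_conservation(self, rng):
        x = rng.standard_normal((2, 4, 12, 12))
        s = haar_dwt2d(x)
        energy_in = (x**2).sum()
        assert abs(s.energy() - energy_in) / energy_in < 1e-4

    def test_nonfinite_input_rejected_with_location(self):
        x = np.zeros((1, 2, 4, 4))
        x[0, 1, 2, 3] = np.nan
        with pytest.raises(ValidationError, match="channel=1"):
            haar_dwt2d(x)


class TestSynthesis:
    @pytest.mark.parametrize("shape", [(4, 8, 32, 32), (1, 1, 4, 4), (2, 3, 7, 9),
                                       (1, 2, 5, 16)])
    def test_perfect_reconstruction(self, shape, rng):
        x = rng.standard_normal(shape)
        y = haar_iwt2d(haar_dwt2d(x))
        assert np.abs(y.data - x).max() < 1e-5

    def test_zero_subbands_give_zero(self):
        z = np.zeros((1, 1, 2, 2))
        out = haar_iwt2d(WaveletSubbands(z, z, z, z))
        np.testing.assert_array_equal(out.data, np.zeros((1, 1, 4, 4)))

    def test_inverse_of_worked_example(self):
        one = lambda v: np.full((1, 1, 1, 1), v)
        out = haar_iwt2d(WaveletSubbands(one(5.0), one(-1.0), one(-2.0), one(0.0)))
        np.testing.assert_allclose(out.data[0, 0], [[1.0, 2.0], [3.0, 4.0]])

    def test_mismatched_member_shapes_rejected(self):
        good = np.zeros((1, 1, 2, 2))
        bad = np.zeros((1, 1, 3, 2))
        with pytest.raises(ValidationError, match="shapes differ"):
            WaveletSubbands(good, good, good, bad)

    def test_transform_is_differentiable(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 4, 4)), requires_grad=True)
        y = haar_iwt2d(haar_dwt2d(x))
        (y * y).sum().backward()
        # round trip is the identity, so the gradient of sum(y^2) is 2x
        np.testing.assert_allclose(x.grad, 2 * x.data, atol=1e-10)


class TestWtConvBlock:
    def test_identity_configuration(self, rng):
        x = rng.standard_normal((2, 3, 8, 8))
        blk = WtConv(3)
        blk.set_identity()
        assert np.abs(wtconv_forward(x, blk).data - x).max() < 1e-5

    def test_zero_kernels_give_zero(self, rng):
        blk = WtConv(2)
        blk.set_zero()
        out = blk(rng.standard_normal((1, 2, 6, 6)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_explicit_sequential_composition(self, rng):
        x = rng.standard_normal((1, 2, 8, 8))
        blk = WtConv(2, rng=np.random.default_rng(3))
        fused = blk(x).data
        s = haar_dwt2d(x)
        processed = WaveletSubbands(
            ag.depthwise_conv2d(s.ll, blk.conv_ll.weight, blk.conv_ll.bias),
            ag.depthwise_conv2d(s.lh, blk.conv_lh.weight, blk.conv_lh.bias),
            ag.depthwise_conv2d(s.hl, blk.conv_hl.weight, blk.conv_hl.bias),
            ag.depthwise_conv2d(s.hh, blk.conv_hh.weight, blk.conv_hh.bias),
            original_size=s.original_size,
        )
        rec = haar_iwt2d(processed)
        ref = ag.depthwise_conv2d(rec, blk.conv_final.weight, blk.conv_final.bias)
        np.testing.assert_allclose(fused, ref.data, atol=1e-12)

    @pytest.mark.parametrize("size", [4, 5, 9, 16, 21, 33])
    def test_shape_preserved_for_even_and_odd_sizes(self, size, rng):
        blk = WtConv(2, rng=np.random.default_rng(0))
        x = rng.standard_normal((1, 2, size, size))
        assert blk(x).shape == x.shape

    def test_channel_mismatch_rejected(self, rng):
        blk = WtConv(4)
        with pytest.raises(ConfigurationError, match="channels"):
            blk(rng.standard_normal((1, 3, 8, 8)))
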