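"""Quantization, distribution-shift fitting and serpentine sampling."""

import numpy as np
import pytest
from scipy import ndimage

from svbdete.autograd import Tensor
from svbdete.dsconv import (C2fDSConvBlock, FeatureMap, QuantSpec,
                            SnakeKernelSpec, c2f_dsconv_forward, dequantize,
                            dsconv_apply, fit_kds, quantization_scales,
                            quantize_vqk, snake_sample_positions)
from svbdete.nn import Bottleneck, snake_conv2d


class TestQuantization:
    @pytest.mark.parametrize("bits, lo, hi", [(2, -2, 1), (4, -8, 7),
                                              (8, -128, 127)])
    def test_integer_range(self, bits, lo, hi, rng):
        spec = QuantSpec(bits=bits, block_size=16)
        wq = quantize_vqk(rng.normal(size=100), spec)
        assert wq.min() >= lo and wq.max() <= hi
        assert wq.dtype.kind == "i"

    def test_on_grid_weights_are_fixed_points(self, rng):
        # integers whose extreme hits the grid edge give a unit scale,
        # so quantization returns them unchanged
        spec = QuantSpec(bits=8, block_size=64)
        w = rng.integers(-127, 128, size=64).astype(float)
        w[0] = 127
        assert np.array_equal(quantization_scales(w, spec), [1.0])
        assert np.array_equal(quantize_vqk(w, spec), w)

    def test_dequantization_error_within_half_step(self, rng):
        spec = QuantSpec(bits=6, block_size=32)
        w = rng.normal(size=96)
        wq = quantize_vqk(w, spec)
        scales = quantization_scales(w, spec)
        recon = np.concatenate([wq[i * 32:(i + 1) * 32] * s
                                for i, s in enumerate(scales)])
        assert np.max(np.abs(recon - w)) <= scales.max() / 2 + 1e-12

    def test_all_zero_block_uses_unit_scale(self):
        spec = QuantSpec(bits=4, block_size=8)
        assert np.array_equal(quantize_vqk(np.zeros(8), spec), np.zeros(8))
        assert quantization_scales(np.zeros(8), spec) == pytest.approx([1.0])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            QuantSpec(bits=1)
        with pytest.raises(ValueError):
            QuantSpec(block_size=0)


class TestKDSFit:
    def test_closed_form_example(self):
        xi, xi_s = fit_kds([1.0, 2.0], [2, 4], block_size=2)
        assert xi == pytest.approx([0.5])
        assert xi_s == pytest.approx([0.0])
        assert np.allclose(dequantize([2, 4], QuantSpec(block_size=2),
                                      xi, xi_s), [1.0, 2.0])

    def test_exact_representation_gives_identity(self, rng):
        w = rng.normal(size=10)
        xi, xi_s = fit_kds(w, w, block_size=10)
        assert xi == pytest.approx([1.0])
        assert xi_s == pytest.approx([0.0], abs=1e-12)

    def test_degenerate_all_zero_quantized(self):
        xi, xi_s = fit_kds([1.0, 3.0], [0, 0], block_size=2)
        assert xi == pytest.approx([1.0])
        assert xi_s == pytest.approx([2.0])

    def test_scale_is_least_squares_minimizer(self, rng):
        # perturbing the fitted scale by +-10% can only increase the
        # residual of the dequantization objective
        for _ in range(120):
            n = int(rng.integers(2, 33))
            w = rng.normal(size=n) * rng.uniform(0.1, 5)
            wq = quantize_vqk(w, QuantSpec(bits=int(rng.choice([2, 4, 8])),
                                           block_size=n))
            xi, _ = fit_kds(w, wq, block_size=n)

            def residual(s):
                return float(np.sum((wq * s - w) ** 2))

            base = residual(xi[0])
            assert base <= residual(xi[0] * 1.1) + 1e-12
            assert base <= residual(xi[0] * 0.9) + 1e-12


class TestSnakePositions:
    def test_zero_offsets_standard_grid(self):
        spec = SnakeKernelSpec(kernel_size=3)
        assert snake_sample_positions((5.0, 7.0), spec) == [
            (4.0, 7.0), (5.0, 7.0), (6.0, 7.0)]

    def test_fractional_offsets(self):
        spec = SnakeKernelSpec(kernel_size=3, offsets=[0.0, 0.5, -0.5])
        assert snake_sample_positions((0.0, 0.0), spec) == [
            (-1.0, 0.0), (0.0, 0.5), (1.0, -0.5)]

    def test_vertical_axis_swaps_roles(self):
        spec = SnakeKernelSpec(kernel_size=3, offsets=[0.25, 0.0, 0.0],
                               axis="vertical")
        assert snake_sample_positions((2.0, 3.0), spec)[0] == (2.25, 2.0)

    def test_offsets_clamped_on_construction(self):
        spec = SnakeKernelSpec(kernel_size=3, offsets=[2.0, 0.0, -3.0],
                               offset_clamp=1.0)
        assert spec.offsets == pytest.approx([1.0, 0.0, -1.0])


class TestDSConvApply:
    def _dense_oracle(self, x, w):
        """Brute-force dense convolution of a (C,H,W) grid with a
        horizontal (Co,Ci,k) kernel, zero padding."""
        co, ci, _ = w.shape
        out = np.zeros((co, x.shape[1], x.shape[2]))
        for o in range(co):
            for c in range(ci):
                out[o] += ndimage.correlate(x[c], w[o, c][None, :],
                                            mode="constant")
        return out

    def test_zero_offsets_match_dense_convolution(self, rng):
        for _ in range(25):
            ci = int(rng.integers(1, 4))
            co = int(rng.integers(1, 4))
            h = int(rng.integers(4, 33))
            w_ = int(rng.integers(4, 33))
            x = rng.normal(size=(ci, h, w_))
            w = rng.normal(size=(co, ci, 3))
            spec = SnakeKernelSpec(kernel_size=3)
            got = dsconv_apply(x, w, spec)
            assert np.allclose(got, self._dense_oracle(x, w), atol=1e-5)

    def test_constant_input_stays_constant_in_interior(self, rng):
        x = np.full((1, 12, 12), 3.0)
        w = rng.normal(size=(1, 1, 3))
        spec = SnakeKernelSpec(kernel_size=3, offsets=[0.3, -0.6, 0.9])
        out = dsconv_apply(x, w, spec)
        interior = out[0, 2:-2, 2:-2]
        assert np.allclose(interior, interior[0, 0], atol=1e-5)

    def test_quantized_path_exact_on_representable_weights(self, rng):
        # weights on the b=8 integer grid times a scale hit the grid
        # exactly, so KDS/CDS reconstruct them and outputs agree
        w_int = rng.integers(-127, 128, size=(2, 2, 3)).astype(float)
        # every block of 4 contains a grid-edge value, so scales are 1
        w_int.flat[0] = 127
        w_int.flat[4] = -127
        w_int.flat[8] = 127
        x = rng.normal(size=(2, 10, 10))
        spec = SnakeKernelSpec(kernel_size=3, offsets=[0.5, 0.0, -0.5])
        quant = QuantSpec(bits=8, block_size=4)
        assert np.allclose(dsconv_apply(x, w_int, spec, quant),
                           dsconv_apply(x, w_int, spec), atol=1e-5)

    def test_matches_trainable_layer_path(self, rng):
        # independent code path: the autograd snake layer must agree
        # with the functional numpy implementation
        x = rng.normal(size=(2, 9, 11)).astype(np.float32)
        w = rng.normal(size=(3, 2, 3)).astype(np.float32)
        offsets = np.array([0.4, -0.2, 0.7], dtype=np.float32)
        spec = SnakeKernelSpec(kernel_size=3, offsets=offsets)
        functional = dsconv_apply(x, w, spec)
        layer = snake_conv2d(Tensor(x[None]), Tensor(w), Tensor(offsets),
                             "horizontal").data[0]
        assert np.allclose(functional, layer, atol=1e-4)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dsconv_apply(rng.normal(size=(2, 8, 8)),
                         rng.normal(size=(1, 3, 3)), SnakeKernelSpec())


class TestC2fDSConv:
    def test_spatial_dims_preserved(self, rng):
        block = C2fDSConvBlock(4, 6, n=2, seed=0)
        fm = FeatureMap(rng.normal(size=(4, 12, 16)).astype(np.float32))
        out = c2f_dsconv_forward(fm, block)
        assert out.values.shape == (6, 12, 16)

    def test_impulse_support_tracks_receptive_field(self):
        # zero-offset snake bottlenecks have a 1-cell radius per axis
        # per bottleneck; an impulse may not spread further than that
        n = 1
        block = C2fDSConvBlock(2, 2, n=n, seed=3)
        x = np.zeros((2, 15, 15), dtype=np.float32)
        x[:, 7, 7] = 1.0
        out = c2f_dsconv_forward(FeatureMap(x), block).values
        support = np.argwhere(np.abs(out).sum(axis=0) > 1e-7)
        assert support.size > 0
        radius = np.abs(support - 7).max()
        assert radius <= n

    def test_parameter_count_grows_by_one_bottleneck(self):
        cout = 8
        b1 = C2fDSConvBlock(cout, cout, n=1, seed=0)
        b2 = C2fDSConvBlock(cout, cout, n=2, seed=0)
        mid = cout // 2
        extra_bottleneck = Bottleneck(mid, mid, snake=True).num_parameters()
        # the post-concat projection also widens by `mid` input channels
        # of its single-tap kernel: cout*mid extra weights
        assert b2.num_parameters() - b1.num_parameters() \
            == extra_bottleneck + cout * mid

    def test_channel_mismatch_rejected(self, rng):
        block = C2fDSConvBlock(4, 4, n=1)
        with pytest.raises(ValueError):
            c2f_dsconv_forward(FeatureMap(rng.normal(size=(3, 8, 8))), block)
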