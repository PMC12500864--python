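"""Colour conversion, entropy weighting and channel-gradient fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcge_frost.color_gradient import (
    ColorImage,
    ColorSpace,
    EntropyWeights,
    GradientMap,
    entropy_weights,
    fuse_color_gradients,
    hsv_to_rgb,
    image_entropy,
    laplacian_gradient,
    rgb_to_hsv,
)


def _rgb(arr):
    return ColorImage(np.asarray(arr, dtype=np.uint8), ColorSpace.RGB)


class TestRgbToHsv:
    def test_black_has_zero_value(self):
        hsv = rgb_to_hsv(_rgb(np.zeros((3, 3, 3))))
        assert (hsv.pixels[:, :, 2] == 0).all()

    def test_pure_red_anchor(self):
        img = _rgb(np.tile([255, 0, 0], (2, 2, 1)))
        hsv = rgb_to_hsv(img)
        assert (hsv.pixels == [0, 255, 255]).all()

    def test_matches_reference_converter_on_random_input(self, rng):
        from skimage import color as skcolor

        px = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
        ours = rgb_to_hsv(_rgb(px)).pixels
        ref = np.round(skcolor.rgb2hsv(px / 255.0) * 255).astype(np.uint8)
        np.testing.assert_array_equal(ours, ref)

    def test_round_trip_within_hue_quantization(self, rng):
        px = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
        back = hsv_to_rgb(rgb_to_hsv(_rgb(px))).pixels
        assert np.abs(back.astype(int) - px.astype(int)).max() <= 4

    def test_rejects_wrong_space(self):
        hsv = ColorImage(np.zeros((2, 2, 3), dtype=np.uint8), ColorSpace.HSV)
        with pytest.raises(ValueError):
            rgb_to_hsv(hsv)


class TestLaplacianGradient:
    def test_zero_on_constant(self):
        out = laplacian_gradient(np.full((6, 6), 128.0))
        assert (out.values == 0).all()

    def test_single_bright_pixel_response(self):
        ch = np.zeros((5, 5))
        ch[2, 2] = 255.0
        out = laplacian_gradient(ch).values
        assert out[2, 2] == 4 * 255
        for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
            assert out[r, c] == 255
        assert out.sum() == 4 * 255 + 4 * 255

    def test_step_edge_localized_to_flanking_columns(self):
        ch = np.zeros((4, 6))
        ch[:, 3:] = 200.0
        out = laplacian_gradient(ch).values
        nonzero_cols = np.unique(np.nonzero(out)[1])
        np.testing.assert_array_equal(nonzero_cols, [2, 3])
        assert (out[:, 2] == 200).all() and (out[:, 3] == 200).all()

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            laplacian_gradient(np.zeros((0, 3)))


class TestImageEntropy:
    def test_constant_channel_is_zero(self):
        assert image_entropy(np.full((8, 8), 77.0)) == 0.0

    def test_uniform_256_level_channel_is_eight_bits(self):
        ch = np.arange(256, dtype=np.float64).reshape(16, 16)
        assert image_entropy(ch) == pytest.approx(8.0)

    def test_two_level_example(self):
        ch = np.array([[0.0, 0.0], [0.0, 255.0]])
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert image_entropy(ch) == pytest.approx(expected)
        assert image_entropy(ch) == pytest.approx(0.8113, abs=1e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_between_zero_and_eight_bits(self, seed):
        ch = np.random.default_rng(seed).integers(0, 256, (8, 8)).astype(float)
        assert 0.0 <= image_entropy(ch) <= 8.0


class TestEntropyWeights:
    def test_identical_channels_get_uniform_weights(self, rng):
        ch = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        hsv = ColorImage(np.stack([ch] * 3, axis=2), ColorSpace.HSV)
        assert entropy_weights(hsv).as_tuple() == pytest.approx((1 / 3,) * 3)

    def test_constant_image_falls_back_to_uniform(self):
        hsv = ColorImage(np.full((4, 4, 3), 9, dtype=np.uint8), ColorSpace.HSV)
        assert entropy_weights(hsv).as_tuple() == pytest.approx((1 / 3,) * 3)

    def test_one_two_one_bit_channels_normalize_to_quarters(self):
        # H: two levels half/half -> 1 bit; S: four levels -> 2 bits; V: 1 bit
        h = np.repeat([0, 255], 8).reshape(4, 4)
        s = np.repeat([0, 85, 170, 255], 4).reshape(4, 4)
        hsv = ColorImage(np.stack([h, s, h], axis=2).astype(np.uint8), ColorSpace.HSV)
        assert entropy_weights(hsv).as_tuple() == pytest.approx((0.25, 0.5, 0.25))

    def test_weights_always_sum_to_one(self, rng):
        for _ in range(10):
            px = rng.integers(0, 256, (6, 6, 3)).astype(np.uint8)
            w = entropy_weights(ColorImage(px, ColorSpace.HSV))
            assert sum(w.as_tuple()) == pytest.approx(1.0, abs=1e-9)


class TestFuseColorGradients:
    def test_degenerate_weight_returns_first_map(self, rng):
        maps = [GradientMap(rng.random((5, 5))) for _ in range(3)]
        fused = fuse_color_gradients(*maps, EntropyWeights(1.0, 0.0, 0.0))
        np.testing.assert_array_equal(fused.values, maps[0].values)

    def test_uniform_weights_average_constants(self):
        maps = [GradientMap(np.full((3, 3), v)) for v in (3.0, 6.0, 9.0)]
        fused = fuse_color_gradients(*maps, EntropyWeights(1 / 3, 1 / 3, 1 / 3))
        np.testing.assert_allclose(fused.values, 6.0)

    def test_matches_per_pixel_loop_exactly(self, rng):
        g = [GradientMap(rng.random((8, 8))) for _ in range(3)]
        w = EntropyWeights(0.25, 0.5, 0.25)
        fused = fuse_color_gradients(*g, w)
        expected = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = (
                    0.25 * g[0].values[i, j]
                    + 0.5 * g[1].values[i, j]
                    + 0.25 * g[2].values[i, j]
                )
        np.testing.assert_array_equal(fused.values, expected)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.0, 10.0), st.integers(0, 2**31 - 1))
    def test_linear_in_scalar_scaling(self, a, seed):
        r = np.random.default_rng(seed)
        g = [r.random((4, 4)) for _ in range(3)]
        w = EntropyWeights(0.2, 0.3, 0.5)
        scaled = fuse_color_gradients(*(GradientMap(a * x) for x in g), w)
        base = fuse_color_gradients(*(GradientMap(x) for x in g), w)
        np.testing.assert_allclose(scaled.values, a * base.values, rtol=1e-12, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        a = GradientMap(np.zeros((3, 3)))
        b = GradientMap(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            fuse_color_gradients(a, a, b, EntropyWeights(1 / 3, 1 / 3, 1 / 3))


class TestDomainTypes:
    def test_entropy_weights_must_normalize(self):
        with pytest.raises(ValueError):
            EntropyWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            EntropyWeights(-0.2, 0.6, 0.6)

    def test_gradient_map_rejects_negative(self):
        with pytest.raises(ValueError):
            GradientMap(np.array([[-1.0, 0.0]]))

    def test_color_image_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            ColorImage(np.zeros((4, 4), dtype=np.uint8), ColorSpace.RGB)
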