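"""13-tap directional gradients, Sobel magnitude and the final fusion."""

import numpy as np
import pytest

from mcge_frost.color_gradient import EntropyWeights, GradientMap
from mcge_frost.edge_gradient import (
    EdgeKernel,
    FusionParams,
    default_edge_kernel,
    directional_gradient,
    edge_magnitude,
    fuse_gradients,
    sobel_magnitude,
)


class TestEdgeKernel:
    def test_default_kernel_satisfies_invariants(self):
        t = default_edge_kernel().taps
        np.testing.assert_allclose(t, -t[::-1])
        assert t[6] == 0
        assert abs(t.sum()) < 1e-12
        # unit response to a unit ramp: sum i * t[i] = 1
        assert np.dot(np.arange(-6, 7), t) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "taps",
        [
            np.ones(13),                      # not antisymmetric
            np.arange(-6, 7) / 182.0 + 1e-3,  # nonzero sum
            np.zeros(7),                      # wrong length
        ],
    )
    def test_invalid_kernels_rejected(self, taps):
        with pytest.raises(ValueError):
            EdgeKernel(taps)


class TestDirectionalGradient:
    def test_zero_on_constant(self):
        out = directional_gradient(np.full((8, 20), 100.0), "x")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_unit_ramp_gives_unit_interior_response(self):
        ramp = np.tile(np.arange(20, dtype=np.float64), (5, 1))
        out = directional_gradient(ramp, "x")
        np.testing.assert_allclose(out[:, 6:-6], 1.0)

    def test_y_axis_is_transpose_of_x_axis(self, rng):
        ch = rng.integers(0, 256, (10, 14)).astype(np.float64)
        np.testing.assert_array_equal(
            directional_gradient(ch.T, "y"), directional_gradient(ch, "x").T
        )

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            directional_gradient(np.zeros((3, 3)), "z")


class TestEdgeMagnitude:
    def test_one_sided_case(self, rng):
        h_y = rng.normal(size=(6, 6))
        out = edge_magnitude(np.zeros((6, 6)), h_y)
        np.testing.assert_array_equal(out.values, np.abs(h_y))

    def test_pointwise_max_of_absolutes(self):
        out = edge_magnitude(np.array([[-3.0]]), np.array([[2.0]]))
        assert out.values[0, 0] == 3.0

    def test_matches_per_pixel_loop(self, rng):
        hx = rng.normal(size=(8, 8))
        hy = rng.normal(size=(8, 8))
        out = edge_magnitude(hx, hy).values
        for i in range(8):
            for j in range(8):
                assert out[i, j] == max(abs(hx[i, j]), abs(hy[i, j]))


class TestSobelMagnitude:
    def test_zero_on_constant(self):
        assert (sobel_magnitude(np.full((7, 7), 42.0)).values == 0).all()

    def test_vertical_step_response(self):
        ch = np.zeros((6, 6))
        ch[:, 3:] = 200.0
        out = sobel_magnitude(ch).values
        # x-kernel weights (1, 2, 1) against the 200 step -> 4 * 200
        np.testing.assert_allclose(out[:, 2], 800.0)
        np.testing.assert_allclose(out[:, 3], 800.0)
        np.testing.assert_allclose(out[:, :2], 0.0)

    def test_rotation_invariance_of_magnitude(self, rng):
        ch = rng.integers(0, 256, (9, 9)).astype(np.float64)
        rot = np.rot90(ch)
        np.testing.assert_allclose(
            np.rot90(sobel_magnitude(ch).values), sobel_magnitude(rot).values
        )


class TestFuseGradients:
    def _ew_uniform(self):
        return EntropyWeights(1 / 3, 1 / 3, 1 / 3)

    def test_lambda_zero_reduces_to_table_weighted_color_fusion(self, rng):
        # maps with max 1 so the per-map rescaling is the identity
        g = [rng.random((6, 6)) for _ in range(3)]
        for x in g:
            x[0, 0] = 1.0
        zero = GradientMap(np.zeros((6, 6)))
        params = FusionParams(edge_emphasis=0.0)
        fused = fuse_gradients(
            tuple(GradientMap(x) for x in g), self._ew_uniform(), params, zero, zero
        )
        expected = 0.2 * g[0] + 0.48 * g[1] + 0.32 * g[2]
        np.testing.assert_allclose(fused.values, expected, atol=1e-12)

    def test_edge_only_contribution(self):
        zero = GradientMap(np.zeros((4, 4)))
        one = GradientMap(np.ones((4, 4)))
        fused = fuse_gradients(
            (zero, zero, zero), self._ew_uniform(), FusionParams(), one, one
        )
        np.testing.assert_allclose(fused.values, 1.4)

    def test_matches_per_pixel_loop_exactly(self, rng):
        g = [rng.random((8, 8)) for _ in range(3)]
        sob = rng.random((8, 8))
        lap = rng.random((8, 8))
        ew = EntropyWeights(0.2, 0.5, 0.3)
        params = FusionParams()
        fused = fuse_gradients(
            tuple(GradientMap(x) for x in g), ew, params, GradientMap(sob), GradientMap(lap)
        )
        wc = np.array([0.5, 1.2, 0.8])
        eps = np.array([0.2, 0.5, 0.3])
        eff = wc * eps
        eff = eff / eff.sum()
        gn = [x / x.max() for x in g]
        sn, ln = sob / sob.max(), lap / lap.max()
        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                acc = 0.0
                for c in range(3):
                    acc += eff[c] * gn[c][i, j]
                acc += 0.7 * (sn[i, j] + ln[i, j])
                expected[i, j] = acc
        np.testing.assert_array_equal(fused.values, expected)

    def test_zero_where_all_components_zero(self, rng):
        g = [rng.random((6, 6)) for _ in range(3)]
        sob = rng.random((6, 6))
        lap = rng.random((6, 6))
        for x in (*g, sob, lap):
            x[2, 2] = 0.0
        fused = fuse_gradients(
            tuple(GradientMap(x) for x in g),
            self._ew_uniform(),
            FusionParams(),
            GradientMap(sob),
            GradientMap(lap),
        )
        assert fused.values[2, 2] == 0.0
        assert (fused.values >= 0).all()

    def test_degenerate_entropy_collapses_onto_single_channel(self, rng):
        g = [rng.random((4, 4)) for _ in range(3)]
        for x in g:
            x[0, 0] = 1.0
        zero = GradientMap(np.zeros((4, 4)))
        fused = fuse_gradients(
            tuple(GradientMap(x) for x in g),
            EntropyWeights(0.0, 0.0, 1.0),
            FusionParams(edge_emphasis=0.0),
            zero,
            zero,
        )
        # with eps = (0, 0, 1) the effective weights collapse onto V
        np.testing.assert_allclose(fused.values, g[2], atol=1e-12)


class TestFusionParams:
    def test_defaults_are_the_recommended_operating_point(self):
        p = FusionParams()
        assert (p.hue_weight, p.saturation_weight, p.value_weight) == (0.5, 1.2, 0.8)
        assert p.edge_emphasis == 0.7
        assert p.morph_threshold == 0.2
        assert p.kernel_sizes == [3, 5]
        assert p.iterations == 5

    def test_round_trip_through_serialization(self):
        p = FusionParams()
        assert FusionParams(**p.model_dump()) == p

    def test_out_of_range_values_rejected_by_key(self):
        with pytest.raises(ValueError, match="saturation_weight"):
            FusionParams(saturation_weight=-1.0)
        with pytest.raises(ValueError, match="kernel_sizes"):
            FusionParams(kernel_sizes=[4])
        with pytest.raises(ValueError, match="iterations"):
            FusionParams(iterations=50)

    def test_threshold_outside_recommended_band_warns(self):
        with pytest.warns(UserWarning):
            FusionParams(morph_threshold=0.05)
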