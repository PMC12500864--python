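"""Entropy-weighted HSV colour-gradient extraction.

Frost crystals and leaf tissue separate far better in HSV space than in
RGB: frost is bright and desaturated, healthy leaf tissue is green and
saturated.  This module converts RGB leaf images to HSV, extracts a
Laplacian gradient magnitude per channel, and fuses the three channel
gradients into a single map using weights proportional to each channel's
histogram entropy, so the most informative channel dominates.

All channels live on a uniform 8-bit [0, 255] scale, including hue
(rescaled from its native cyclic range).  Hue cyclicity is ignored in
gradient computation; red-adjacent hues may therefore show artificial
gradients, a known limitation that does not affect green foliage.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

__all__ = [
    "ColorSpace",
    "ColorImage",
    "GradientMap",
    "EntropyWeights",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "laplacian_gradient",
    "image_entropy",
    "entropy_weights",
    "fuse_color_gradients",
    "save_gradient_png",
]

#: 3x3 four-neighbour discrete Laplacian stencil.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


class ColorSpace(str, enum.Enum):
    RGB = "RGB"
    HSV = "HSV"


def _validate_channel(channel: np.ndarray) -> np.ndarray:
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("channel must be a non-empty 2-D array")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return arr


@dataclass(frozen=True)
class ColorImage:
    """An 8-bit three-channel image with a declared colour space."""

    pixels: np.ndarray
    space: ColorSpace

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        object.__setattr__(self, "space", ColorSpace(self.space))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as a float array in [0, 255]."""
        return self.pixels[:, :, index].astype(np.float64)


@dataclass(frozen=True)
class GradientMap:
    """A non-negative gradient-magnitude field with a provenance tag."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("gradient map must be a non-empty 2-D array")
        if vals.min() < 0:
            raise ValueError("gradient map must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class EntropyWeights:
    """Per-channel fusion weights, non-negative and summing to one."""

    w_h: float
    w_s: float
    w_v: float

    def __post_init__(self) -> None:
        if min(self.w_h, self.w_s, self.w_v) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_h + self.w_s + self.w_v - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_h, self.w_s, self.w_v)


def rgb_to_hsv(img: ColorImage) -> ColorImage:
    """Convert an RGB image to HSV with all channels scaled to [0, 255].

    Hue is rescaled from its native cyclic range onto the same 8-bit
    scale as saturation and value so that channel weights remain
    comparable.  The inverse (:func:`hsv_to_rgb`) recovers the original
    RGB within ±4 per channel; the residual is dominated by 8-bit hue
    quantization.
    """
    if img.space is not ColorSpace.RGB:
        raise ValueError("rgb_to_hsv expects an RGB image")
    hsv = _skcolor.rgb2hsv(img.pixels.astype(np.float64) / 255.0)
    out = np.round(hsv * 255.0).clip(0, 255).astype(np.uint8)
    return ColorImage(out, ColorSpace.HSV)


def hsv_to_rgb(img: ColorImage) -> ColorImage:
    """Inverse of :func:`rgb_to_hsv` (up to 8-bit quantization)."""
    if img.space is not ColorSpace.HSV:
        raise ValueError("hsv_to_rgb expects an HSV image")
    rgb = _skcolor.hsv2rgb(img.pixels.astype(np.float64) / 255.0)
    out = np.round(rgb * 255.0).clip(0, 255).astype(np.uint8)
    return ColorImage(out, ColorSpace.RGB)


def laplacian_gradient(channel: np.ndarray) -> GradientMap:
    """Absolute response of the 4-neighbour Laplacian, replicate-padded."""
    arr = _validate_channel(channel)
    resp = ndimage.convolve(arr, LAPLACIAN_KERNEL, mode="nearest")
    return GradientMap(np.abs(resp), source="laplacian")


def image_entropy(channel: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-level grey histogram.

    Returns a value in [0, 8]: 0 for a constant channel, 8 for a
    perfectly uniform histogram over all 256 levels.
    """
    arr = _validate_channel(channel)
    levels = np.round(arr).astype(np.int64).ravel()
    counts = np.bincount(levels, minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def entropy_weights(hsv: ColorImage) -> EntropyWeights:
    """Channel weights proportional to per-channel histogram entropy.

    Degenerate case: a fully constant image (all entropies zero) yields
    uniform weights (1/3, 1/3, 1/3).
    """
    if hsv.space is not ColorSpace.HSV:
        raise ValueError("entropy_weights expects an HSV image")
    ent = np.array([image_entropy(hsv.channel(i)) for i in range(3)])
    total = ent.sum()
    if total == 0:
        return EntropyWeights(1 / 3, 1 / 3, 1 / 3)
    w = ent / total
    return EntropyWeights(float(w[0]), float(w[1]), float(w[2]))


def fuse_color_gradients(
    g_h: GradientMap, g_s: GradientMap, g_v: GradientMap, w: EntropyWeights
) -> GradientMap:
    """Pixelwise weighted sum of the three channel gradient maps."""
    if not (g_h.shape == g_s.shape == g_v.shape):
        raise ValueError("gradient maps must share a shape")
    fused = w.w_h * g_h.values + w.w_s * g_s.values + w.w_v * g_v.values
    return GradientMap(fused, source="fused:color")


def save_gradient_png(gmap: GradientMap, path: str | Path) -> None:
    """Export a gradient map as 16-bit PNG with a JSON scale sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    peak = float(gmap.values.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    iio.imwrite(path, np.round(gmap.values * scale).astype(np.uint16))
    sidecar = {"scale": scale, "max_value": peak, "source": gmap.source}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
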