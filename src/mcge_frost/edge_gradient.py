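"""Directional edge gradients and the final colour+edge gradient fusion.

Besides the per-channel Laplacian magnitudes of
:mod:`~mcge_frost.color_gradient`, the segmenter uses a 13-tap
antisymmetric derivative kernel (applied along x and y, combined by the
per-pixel maximum of absolute responses) as an edge-detail diagnostic,
plus standard Sobel and Laplacian edge terms that enter the final fused
gradient

    G_fused = sum_c (w_c * eps_c / Z) * grad(I_c) + lambda * (G_sobel + G_laplacian)

where ``w_c`` are fixed channel weights, ``eps_c`` the adaptive entropy
weights, ``Z = sum_c w_c*eps_c`` renormalizes the combined channel
weights to one, and ``lambda`` balances colour against edge gradients.
Component maps are individually rescaled to [0, 1] by their own maxima
before fusion so that ``lambda`` trades off comparable magnitudes (raw
Laplacian and Sobel scales differ by orders of magnitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy import ndimage

from .color_gradient import EntropyWeights, GradientMap, _validate_channel

__all__ = [
    "EdgeKernel",
    "FusionParams",
    "default_edge_kernel",
    "directional_gradient",
    "edge_magnitude",
    "sobel_magnitude",
    "fuse_gradients",
]


@dataclass(frozen=True)
class EdgeKernel:
    """13 antisymmetric derivative taps t[-6..6] with zero sum."""

    taps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.taps, dtype=np.float64)
        if t.shape != (13,):
            raise ValueError("kernel must have exactly 13 taps")
        if not np.allclose(t, -t[::-1], atol=1e-12) or t[6] != 0:
            raise ValueError("kernel must be antisymmetric with t[0] = 0")
        if abs(t.sum()) > 1e-12:
            raise ValueError("kernel taps must sum to zero")
        object.__setattr__(self, "taps", t)


def default_edge_kernel() -> EdgeKernel:
    """Least-squares (Savitzky-Golay) first-derivative taps t[i] = i/182.

    182 = sum of i^2 over i in [-6, 6]; the kernel responds exactly 1.0
    to a unit ramp.
    """
    i = np.arange(-6, 7, dtype=np.float64)
    return EdgeKernel(i / 182.0)


class FusionParams(BaseModel):
    """Tunable weights and morphology settings of the fused pipeline.

    Defaults are the recommended operating point: channel weights
    (0.5, 1.2, 0.8) for H/S/V, edge emphasis 0.7, noise-suppression
    threshold 0.2 on the [0, 1] refined map, kernel sizes [3, 5] and a
    refinement budget of 5 iterations.
    """

    hue_weight: float = Field(default=0.5, gt=0)
    saturation_weight: float = Field(default=1.2, gt=0)
    value_weight: float = Field(default=0.8, gt=0)
    edge_emphasis: float = Field(default=0.7, ge=0)
    morph_threshold: float = Field(default=0.2, gt=0, lt=1)
    kernel_sizes: list[int] = Field(default_factory=lambda: [3, 5])
    iterations: int = Field(default=5, ge=1, le=10)
    enable_morphology: bool = True

    @field_validator("morph_threshold")
    @classmethod
    def _warn_threshold(cls, v: float) -> float:
        if not 0.1 <= v <= 0.4:
            warnings.warn(
                f"morph_threshold={v} lies outside the recommended [0.1, 0.4]",
                stacklevel=2,
            )
        return v

    @field_validator("kernel_sizes")
    @classmethod
    def _check_kernels(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("kernel_sizes must be non-empty")
        for k in v:
            if k not in (3, 5, 7):
                raise ValueError(f"kernel_sizes entries must be in {{3, 5, 7}}, got {k}")
        return v

    def channel_weights(self) -> np.ndarray:
        return np.array(
            [self.hue_weight, self.saturation_weight, self.value_weight]
        )


def directional_gradient(
    channel: np.ndarray, axis: str, kernel: EdgeKernel | None = None
) -> np.ndarray:
    """Signed 1-D correlation of the channel with the 13-tap kernel.

    ``axis='x'`` differentiates along image columns (horizontal),
    ``axis='y'`` along rows; borders are replicate-padded.  Because the
    kernel is antisymmetric the response on any constant image is zero.
    """
    arr = _validate_channel(channel)
    if kernel is None:
        kernel = default_edge_kernel()
    if axis == "x":
        ax = 1
    elif axis == "y":
        ax = 0
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return ndimage.correlate1d(arr, kernel.taps, axis=ax, mode="nearest")


def edge_magnitude(h_x: np.ndarray, h_y: np.ndarray) -> GradientMap:
    """Per-pixel max of the absolute directional responses."""
    h_x = np.asarray(h_x, dtype=np.float64)
    h_y = np.asarray(h_y, dtype=np.float64)
    if h_x.shape != h_y.shape:
        raise ValueError("directional responses must share a shape")
    return GradientMap(np.maximum(np.abs(h_x), np.abs(h_y)), source="edge:max")


def sobel_magnitude(channel: np.ndarray) -> GradientMap:
    """Standard 3x3 Sobel magnitude sqrt(Gx^2 + Gy^2), replicate-padded."""
    arr = _validate_channel(channel)
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    return GradientMap(np.hypot(gx, gy), source="sobel")


def _unit_rescale(values: np.ndarray) -> np.ndarray:
    peak = values.max()
    return values / peak if peak > 0 else values


def fuse_gradients(
    color_grads: tuple[GradientMap, GradientMap, GradientMap],
    ew: EntropyWeights,
    params: FusionParams,
    sobel: GradientMap,
    laplacian: GradientMap,
) -> GradientMap:
    """Assemble the final fused colour+edge gradient map.

    Effective channel weights are ``w_c * eps_c`` renormalized to sum
    one, honouring both the fixed channel weights and the adaptive
    entropy weights; either pure scheme is recoverable by setting all
    ``w_c`` equal or forcing uniform entropies.  Every component map is
    rescaled to [0, 1] by its own maximum first.
    """
    g_h, g_s, g_v = color_grads
    shapes = {g_h.shape, g_s.shape, g_v.shape, sobel.shape, laplacian.shape}
    if len(shapes) != 1:
        raise ValueError("all component maps must share a shape")

    wc = params.channel_weights()
    eps = np.array(ew.as_tuple())
    eff = wc * eps
    z = eff.sum()
    if z == 0:
        # all-zero entropies: fall back to the fixed weights alone
        eff = wc / wc.sum()
    else:
        eff = eff / z

    fused = np.zeros(g_h.shape, dtype=np.float64)
    for w, g in zip(eff, (g_h, g_s, g_v)):
        fused += w * _unit_rescale(g.values)
    fused += params.edge_emphasis * (
        _unit_rescale(sobel.values) + _unit_rescale(laplacian.values)
    )
    return GradientMap(fused, source="fused:color+edge")
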