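"""Comparison segmenters: ExG, Otsu, K-means, HSV boxes, isodata.

These are the classical single-cue methods the gradient-enhancement
pipeline is benchmarked against.  Each fails in a characteristic way on
cluttered scenes: ExG needs a non-green background, Otsu needs a clean
grey-level gap, K-means and plain isodata over-segment soil and weed
texture, and fixed HSV boxes confuse weeds with leaf tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .color_gradient import ColorImage, ColorSpace, rgb_to_hsv
from .morphology import BinaryMask, MaskRole
from .segmentation import LabelMap

__all__ = [
    "HsvRange",
    "DEFAULT_FROST_BOX",
    "DEFAULT_LEAF_BOX",
    "exg_map",
    "exg_segment",
    "otsu_threshold",
    "otsu_segment",
    "kmeans_segment",
    "hsv_threshold_segment",
]


@dataclass(frozen=True)
class HsvRange:
    """Axis-aligned inclusive box in HSV space ([0, 255] per channel).

    Hue wrap-around is not supported: lo <= hi is required per channel.
    """

    h: tuple[int, int] = (0, 255)
    s: tuple[int, int] = (0, 255)
    v: tuple[int, int] = (0, 255)

    def __post_init__(self) -> None:
        for name in ("h", "s", "v"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi <= 255")

    def contains(self, hsv_pixels: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an (H, W, 3) HSV array."""
        out = np.ones(hsv_pixels.shape[:2], dtype=bool)
        for i, name in enumerate(("h", "s", "v")):
            lo, hi = getattr(self, name)
            ch = hsv_pixels[:, :, i]
            out &= (ch >= lo) & (ch <= hi)
        return out


# Seeded from the characteristic intervals of frosted-leaf imagery:
# frost is bright (V in [150, 255]) and desaturated (S in [0, 100]);
# leaf hues concentrate in [50, 120] on the 8-bit hue scale.
DEFAULT_FROST_BOX = HsvRange(s=(0, 100), v=(150, 255))
DEFAULT_LEAF_BOX = HsvRange(h=(50, 120))


def exg_map(img: ColorImage) -> np.ndarray:
    """Excess-green index 2g - r - b on chromaticity-normalized channels.

    r = R/(R+G+B) etc.; black pixels (zero denominator) get ExG 0.
    The index lies in [-1, 2], with 2 at pure green.
    """
    if img.space is not ColorSpace.RGB:
        raise ValueError("exg expects an RGB image")
    rgb = img.pixels.astype(np.float64)
    total = rgb.sum(axis=2)
    safe = np.where(total == 0, 1.0, total)
    r, g, b = (np.where(total == 0, 0.0, rgb[:, :, i] / safe) for i in range(3))
    return 2.0 * g - r - b


def exg_segment(img: ColorImage) -> BinaryMask:
    """Vegetation mask: Otsu threshold on the quantized ExG map."""
    exg = exg_map(img)
    # map [-1, 2] onto the 8-bit grid so the histogram search applies
    grey = np.round((exg + 1.0) / 3.0 * 255.0).clip(0, 255)
    t, _ = otsu_segment(grey)
    return BinaryMask((grey > t).astype(np.uint8), MaskRole.LEAF)


def otsu_threshold(grey: np.ndarray) -> float:
    """Exhaustive 0..255 search maximizing between-class variance.

    Ties break toward the lowest threshold.  The returned value t
    defines the foreground as pixels strictly above t.
    """
    arr = np.round(np.asarray(grey, dtype=np.float64)).astype(np.int64).ravel()
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("grey values must lie in [0, 255]")
    if np.unique(arr).size < 2:
        raise ValueError("otsu needs at least 2 distinct grey levels")
    counts = np.bincount(arr, minlength=256).astype(np.float64)
    total = counts.sum()
    p = counts / total
    levels = np.arange(256, dtype=np.float64)
    omega0 = np.cumsum(p)                      # weight of class <= t
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    return float(np.argmax(sigma_b))  # argmax takes the first (lowest) tie


def otsu_segment(grey: np.ndarray) -> tuple[float, BinaryMask]:
    t = otsu_threshold(grey)
    mask = (np.round(np.asarray(grey, dtype=np.float64)) > t).astype(np.uint8)
    return t, BinaryMask(mask, MaskRole.LEAF)


def kmeans_segment(img: ColorImage, k: int = 3, seed: int = 0) -> LabelMap:
    """Lloyd's algorithm on RGB triples, clusters ranked by brightness.

    Clusters are mapped to classes by ascending mean value (V = max of
    the centroid's RGB): darkest -> background (0), brightest -> frost
    (2), everything between -> leaf (1).  Deterministic given the seed.
    """
    if img.space is not ColorSpace.RGB:
        raise ValueError("kmeans_segment expects an RGB image")
    if k < 2:
        raise ValueError("k must be >= 2")
    flat = img.pixels.reshape(-1, 3).astype(np.float64)
    n_colors = np.unique(flat, axis=0).shape[0]
    if k > n_colors:
        raise ValueError(f"k={k} exceeds the {n_colors} distinct colours present")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=100, tol=1e-4,
        random_state=seed,
    ).fit(flat)
    assignments = km.labels_.reshape(img.pixels.shape[:2])
    brightness = km.cluster_centers_.max(axis=1)
    order = np.argsort(brightness, kind="stable")
    class_of = np.empty(k, dtype=np.uint8)
    class_of[order[0]] = 0
    class_of[order[-1]] = 2
    for idx in order[1:-1]:
        class_of[idx] = 1
    return LabelMap(class_of[assignments])


def hsv_threshold_segment(
    img: ColorImage,
    frost_box: HsvRange = DEFAULT_FROST_BOX,
    leaf_box: HsvRange = DEFAULT_LEAF_BOX,
) -> LabelMap:
    """Fixed HSV box classification: frost first, then leaf, else background."""
    hsv = rgb_to_hsv(img) if img.space is ColorSpace.RGB else img
    px = hsv.pixels.astype(np.float64)
    labels = np.zeros(px.shape[:2], dtype=np.uint8)
    leaf = leaf_box.contains(px)
    frost = frost_box.contains(px)
    labels[leaf] = 1
    labels[frost] = 2  # frost box wins on overlap (first-match precedence)
    return LabelMap(labels)
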