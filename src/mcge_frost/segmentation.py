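"""The end-to-end MCGE-Frost segmenter and frost-severity staging.

The pipeline: RGB -> HSV -> per-channel Laplacian gradients -> entropy
weights -> colour+edge gradient fusion (Sobel and Laplacian of the V
channel as edge terms) -> adaptive morphological refinement -> isodata
thresholding of the refined map for the leaf/background boundary ->
within-leaf frost/no-frost split by a whiteness rule (high V, low S).

Severity is reported as the Frost Coverage Ratio (FCR), the percentage
of leaf pixels covered by frost, staged as level I (0, 30], II (30, 60]
or III (60, 100].
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .color_gradient import ColorImage, ColorSpace, GradientMap, entropy_weights, laplacian_gradient, rgb_to_hsv
from .edge_gradient import FusionParams, fuse_gradients, sobel_magnitude
from .morphology import Background, adaptive_refine, morph_op

__all__ = [
    "LabelMap",
    "FrostLevel",
    "FrostReport",
    "NoLeafError",
    "BACKGROUND_LABEL",
    "LEAF_LABEL",
    "FROST_LABEL",
    "iterative_threshold",
    "classify_frost_level",
    "leaf_area",
    "cleaned_leaf_mask",
    "segment",
    "build_report",
]

BACKGROUND_LABEL, LEAF_LABEL, FROST_LABEL = 0, 1, 2

# Whiteness priors for frost pixels on the [0, 255] HSV scale: frost
# crystals brighten V into [150, 255] and stay desaturated (S <= 100).
FROST_V_FLOOR = 150.0
FROST_S_CEILING = 100.0

#: 8-connectivity, matching the dendritic frost morphology.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class NoLeafError(RuntimeError):
    """Raised when no leaf-sized component is found in the image."""


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class labels: 0 background, 1 leaf-no-frost, 2 frost."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        if not np.isin(lab, (0, 1, 2)).all():
            raise ValueError("labels must be drawn from {0, 1, 2}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


class FrostLevel(str, enum.Enum):
    NONE = "NONE"
    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class FrostReport:
    """Quantified frost severity for one image, with provenance."""

    fcr_percent: float
    level: FrostLevel
    a_frost: int
    a_leaf: int
    background: Background
    params_digest: str

    def __post_init__(self) -> None:
        if self.a_leaf <= 0:
            raise ValueError("leaf area must be positive")
        if abs(self.fcr_percent - 100.0 * self.a_frost / self.a_leaf) > 1e-9:
            raise ValueError("fcr_percent inconsistent with pixel counts")
        if classify_frost_level(self.fcr_percent) is not self.level:
            raise ValueError("level inconsistent with fcr_percent")

    def to_dict(self) -> dict:
        return {
            "fcr_percent": self.fcr_percent,
            "level": self.level.value,
            "a_frost": self.a_frost,
            "a_leaf": self.a_leaf,
            "background": self.background.value,
            "params_digest": self.params_digest,
        }


def params_digest(params: FusionParams) -> str:
    blob = json.dumps(params.model_dump(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def iterative_threshold(values: np.ndarray) -> float:
    """Isodata threshold: T <- (mean below + mean above) / 2.

    Starts from the midpoint of the value range and iterates until the
    update falls below half a grey level.  Raises ``ValueError`` on a
    (near-)constant input, which offers no separable classes.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0 or np.unique(arr).size < 2:
        raise ValueError("iterative_threshold needs at least 2 distinct values")
    lo, hi = arr.min(), arr.max()
    t = 0.5 * (lo + hi)
    for _ in range(500):
        below = arr[arr <= t]
        above = arr[arr > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return float(t)


def classify_frost_level(fcr_percent: float) -> FrostLevel:
    """Stage severity: 0 -> NONE, (0,30] -> I, (30,60] -> II, (60,100] -> III."""
    if not 0.0 <= fcr_percent <= 100.0:
        raise ValueError("fcr_percent must lie in [0, 100]")
    if fcr_percent == 0.0:
        return FrostLevel.NONE
    if fcr_percent <= 30.0:
        return FrostLevel.I
    if fcr_percent <= 60.0:
        return FrostLevel.II
    return FrostLevel.III


def cleaned_leaf_mask(labels: LabelMap, background: Background, kernel_size: int = 3) -> np.ndarray:
    """The leaf support used for area accounting.

    Blurred scenes use the label support as-is; soil/weed scenes first
    apply a binary opening (erosion then dilation), which strips
    boundary pixels contaminated by background clutter.
    """
    background = Background(background)
    mask = (labels.labels != BACKGROUND_LABEL).astype(np.uint8)
    if background is Background.BLURRED:
        return mask
    footprint = np.ones((kernel_size, kernel_size), dtype=bool)
    return ndimage.grey_opening(mask, footprint=footprint, mode="nearest").astype(np.uint8)


def leaf_area(labels: LabelMap, background: Background) -> int:
    """Total leaf pixel count under the background's area convention."""
    area = int(cleaned_leaf_mask(labels, background).sum())
    if area == 0:
        raise ValueError("leaf area is zero; FCR undefined")
    return area


# Leaf-contour closure settings per background: (gap-bridging radius
# for the dilate/fill/erode step, cleanup-opening iterations).  Clutter
# degrades the contour progressively: soil texture breaks it into
# longer gaps (larger bridging radius), weed blobs weld onto it
# (aggressive cleanup opening to shave the welded lobes).
_LEAF_CLOSURE: dict[Background, tuple[int, int]] = {
    Background.BLURRED: (3, 0),
    Background.SOIL: (7, 8),
    Background.WEEDS: (3, 20),
}


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _frost_split(v: np.ndarray, s: np.ndarray, leaf: np.ndarray) -> np.ndarray:
    """Within-leaf frost mask: bright (high V) and desaturated (low S).

    Candidate pixels must satisfy the whiteness priors (V >= 150,
    S <= 100).  When the leaf genuinely contains both frosted and clear
    tissue, isodata thresholds on the within-leaf V and S distributions
    tighten the cut adaptively; near-pure leaves (almost no or almost
    all candidates) keep the priors alone, since a unimodal distribution
    gives isodata nothing to separate.
    """
    candidates = leaf & (v >= FROST_V_FLOOR) & (s <= FROST_S_CEILING)
    n_leaf = int(leaf.sum())
    frac = candidates.sum() / n_leaf if n_leaf else 0.0
    t_v, t_s = FROST_V_FLOOR, FROST_S_CEILING
    if 0.02 < frac < 0.98:
        try:
            t_v = max(iterative_threshold(v[leaf]), FROST_V_FLOOR)
            t_s = min(iterative_threshold(s[leaf]), FROST_S_CEILING)
        except ValueError:
            pass  # degenerate within-leaf distribution: keep the priors
    return leaf & (v >= t_v) & (s <= t_s)


def segment(
    img: ColorImage,
    background: Background,
    params: FusionParams | None = None,
    seed: int = 0,
) -> LabelMap:
    """Run the full multi-component gradient-enhancement segmenter.

    Deterministic given (image, params, seed).  Raises
    :class:`NoLeafError` when the largest candidate component covers
    less than 1% of the image.
    """
    if img.space is not ColorSpace.RGB:
        raise ValueError("segment expects an RGB image")
    background = Background(background)
    if params is None:
        params = FusionParams()

    hsv = rgb_to_hsv(img)
    h, s, v = (hsv.channel(i) for i in range(3))

    g_h, g_s, g_v = (laplacian_gradient(c) for c in (h, s, v))
    ew = entropy_weights(hsv)
    sob = sobel_magnitude(v)
    lap = laplacian_gradient(v)
    fused = fuse_gradients((g_h, g_s, g_v), ew, params, sob, lap)

    # Robust normalization: scale by the mean gradient above the
    # isodata cut (the typical strength of a real edge), clipped to 1,
    # so a handful of extreme texture responses cannot set the scale.
    vals = fused.values
    try:
        edge_level = iterative_threshold(vals)
    except ValueError as exc:
        raise NoLeafError("fused gradient map is constant; no leaf detected") from exc
    scale = vals[vals > edge_level].mean()
    norm = GradientMap(np.clip(vals / scale, 0.0, 1.0) if scale > 0 else vals, source="fused:norm")
    suppressed = params.enable_morphology
    refined = adaptive_refine(norm, background, params) if params.enable_morphology else norm
    if suppressed and refined.values.max() == 0:
        # degenerate case: an ideal razor-sharp contour (no noise, no
        # texture junctions) is thinner than the smallest kernel and the
        # refinement wipes the whole map; fall back to the raw fusion
        refined = norm
        suppressed = False

    grey = refined.values * 255.0
    try:
        t_leaf = iterative_threshold(grey)
    except ValueError as exc:
        raise NoLeafError("refined gradient map is constant; no leaf detected") from exc
    if suppressed:
        # isodata overshoots when strong frost texture dominates the
        # surviving histogram; the refinement threshold, already vetted
        # as the edge/noise cut, bounds it from above.
        t_leaf = min(t_leaf, 255.0 * params.morph_threshold)

    edge_mask = grey > t_leaf
    bridge, cleanup = _LEAF_CLOSURE[background]
    # erode one step further than the dilation: the gradient ridge
    # straddles the true edge, so the filled envelope overshoots the
    # leaf by about one pixel all around
    closed = ndimage.binary_erosion(
        ndimage.binary_fill_holes(ndimage.binary_dilation(edge_mask, _STRUCT8, bridge)),
        _STRUCT8,
        bridge + 1,
    )
    leaf = _largest_component(closed)
    if leaf.sum() < 0.01 * leaf.size:
        raise NoLeafError("largest component covers < 1% of the image")
    if cleanup:
        opened = ndimage.binary_opening(leaf, _STRUCT8, iterations=cleanup)
        if opened.any():
            leaf = _largest_component(opened)
    if background is not Background.BLURRED:
        # area-accounting cleanup: strip clutter-contaminated boundary
        # pixels with the same opening that defines leaf_area
        leaf = morph_op(leaf.astype(np.float64), "open", 3).astype(bool)
        if not leaf.any():
            raise NoLeafError("leaf mask vanished under morphological cleanup")

    frost = _frost_split(v, s, leaf)
    labels = np.zeros(leaf.shape, dtype=np.uint8)
    labels[leaf] = LEAF_LABEL
    labels[frost] = FROST_LABEL
    return LabelMap(labels)


def build_report(
    labels: LabelMap, background: Background, params: FusionParams | None = None
) -> FrostReport:
    """Summarize a label map as a :class:`FrostReport`."""
    background = Background(background)
    if params is None:
        params = FusionParams()
    mask = cleaned_leaf_mask(labels, background)
    a_leaf = int(mask.sum())
    if a_leaf == 0:
        raise ValueError("leaf area is zero; FCR undefined")
    a_frost = int(((labels.labels == FROST_LABEL) & (mask == 1)).sum())
    fcr = 100.0 * a_frost / a_leaf
    return FrostReport(
        fcr_percent=fcr,
        level=classify_frost_level(fcr),
        a_frost=a_frost,
        a_leaf=a_leaf,
        background=background,
        params_digest=params_digest(params),
    )
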