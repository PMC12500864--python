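"""Evaluation metrics: FCR, mis-segmentation rate, Dice, average precision.

The mis-segmentation rate R_ms is a count-based relative error — it can
be zero while the predicted pixels sit in the wrong place — whereas the
Dice coefficient measures spatial overlap; reporting both separates
"how much frost" errors from "where" errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .morphology import Background
from .segmentation import FROST_LABEL, LabelMap, cleaned_leaf_mask, leaf_area

__all__ = [
    "EvalPair",
    "frost_coverage_ratio",
    "mis_segmentation_rate",
    "dice",
    "average_precision",
]

TargetClass = Literal["frost", "leaf"]


@dataclass(frozen=True)
class EvalPair:
    """A predicted/ground-truth label-map pair for one image."""

    predicted: LabelMap
    truth: LabelMap
    target_class: TargetClass = "frost"

    def __post_init__(self) -> None:
        if self.predicted.shape != self.truth.shape:
            raise ValueError("predicted and truth label maps must share a shape")
        if self.target_class not in ("frost", "leaf"):
            raise ValueError("target_class must be 'frost' or 'leaf'")

    def _mask(self, labels: LabelMap) -> np.ndarray:
        if self.target_class == "frost":
            return labels.labels == FROST_LABEL
        return labels.labels != 0

    @property
    def predicted_mask(self) -> np.ndarray:
        return self._mask(self.predicted)

    @property
    def truth_mask(self) -> np.ndarray:
        return self._mask(self.truth)


def frost_coverage_ratio(labels: LabelMap, background: Background) -> float:
    """FCR = 100 * A_frost / A_leaf, in percent.

    In soil/weed mode both counts are taken over the morphologically
    cleaned leaf mask, keeping the ratio within [0, 100].
    """
    a_leaf = leaf_area(labels, background)
    mask = cleaned_leaf_mask(labels, Background(background))
    a_frost = int(((labels.labels == FROST_LABEL) & (mask == 1)).sum())
    return 100.0 * a_frost / a_leaf


def mis_segmentation_rate(pairs: Sequence[EvalPair]) -> float:
    """Mean relative pixel-count error |p_s - p_a| / p_a, in percent."""
    if not pairs:
        raise ValueError("mis_segmentation_rate needs at least one pair")
    rates = []
    for i, pair in enumerate(pairs):
        p_a = int(pair.truth_mask.sum())
        if p_a == 0:
            raise ValueError(
                f"pair {i}: ground truth contains no '{pair.target_class}' pixels"
            )
        p_s = int(pair.predicted_mask.sum())
        rates.append(abs(p_s - p_a) / p_a)
    return 100.0 * float(np.mean(rates))


def dice(pairs: Sequence[EvalPair]) -> float:
    """Mean Dice overlap 2|P∩T| / (|P|+|T|) over the target class.

    A pair where both masks are empty counts as perfect agreement (1.0).
    """
    if not pairs:
        raise ValueError("dice needs at least one pair")
    scores = []
    for pair in pairs:
        p = pair.predicted_mask
        t = pair.truth_mask
        denom = int(p.sum()) + int(t.sum())
        if denom == 0:
            scores.append(1.0)
        else:
            scores.append(2.0 * int((p & t).sum()) / denom)
    return float(np.mean(scores))


def average_precision(estimated: Sequence[float], reference: Sequence[float]) -> float:
    """100 * (1 - mean relative error) of estimates against references."""
    est = np.asarray(estimated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.size == 0 or est.shape != ref.shape:
        raise ValueError("estimated and reference must be equal-length and non-empty")
    if (ref <= 0).any():
        raise ValueError("reference values must be positive")
    return 100.0 * (1.0 - float(np.mean(np.abs(est - ref) / ref)))
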