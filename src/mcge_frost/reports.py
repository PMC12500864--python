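"""Benchmark orchestration and report generation.

Runs any of the configured segmenters over a suite of ground-truthed
scenes and aggregates mis-segmentation rate (mean ± SD), Dice overlap
and coverage accuracy per (method x background), with totals taken as
the unweighted mean across backgrounds.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .baselines import (
    exg_segment,
    hsv_threshold_segment,
    kmeans_segment,
    otsu_segment,
)
from .color_gradient import ColorImage
from .edge_gradient import FusionParams
from .metrics import EvalPair, average_precision, dice, frost_coverage_ratio, mis_segmentation_rate
from .morphology import Background
from .segmentation import (
    FrostLevel,
    LabelMap,
    NoLeafError,
    classify_frost_level,
    iterative_threshold,
    segment,
)
from .synthetic import ScenePack

__all__ = ["RunConfig", "METHODS", "predict_labels", "run_benchmark", "render_tables"]

logger = logging.getLogger("mcge_frost")

METHODS = ("mcge", "exg", "otsu", "kmeans", "hsv", "iterative")


class RunConfig(BaseModel):
    """Resolved configuration of a benchmark or segmentation run."""

    methods: list[str] = Field(default_factory=lambda: ["mcge"])
    fusion: FusionParams = Field(default_factory=FusionParams)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML or TOML key-value file; kwargs override keys."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        fusion_keys = set(FusionParams.model_fields)
        fusion = {k: v for k, v in data.items() if k in fusion_keys}
        fusion.update({k: v for k, v in overrides.items() if k in fusion_keys})
        top = {k: v for k, v in data.items() if k not in fusion_keys}
        top.update({k: v for k, v in overrides.items() if k not in fusion_keys})
        if "fusion" in top and isinstance(top["fusion"], dict):
            merged = dict(top.pop("fusion"))
            merged.update(fusion)
            fusion = merged
        return cls(fusion=FusionParams(**fusion), **top)


def _fill_largest(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    struct8 = np.ones((3, 3), dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(filled, structure=struct8)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _bright_split_labels(v: np.ndarray, bright_mask: np.ndarray) -> LabelMap:
    """Leaf = filled largest bright component; frost = its brighter half.

    The adapter both Otsu and plain isodata thresholding use to produce
    three classes from a single grey cue: the global threshold yields a
    foreground mask, and a second threshold within the leaf calls its
    brighter side frost.  This inherits the methods' characteristic
    failure — any within-leaf brightness split is reported as frost.
    """
    leaf = _fill_largest(bright_mask)
    labels = np.zeros(v.shape, dtype=np.uint8)
    labels[leaf] = 1
    if leaf.any():
        inner = v[leaf]
        if np.unique(inner).size >= 2:
            t2 = iterative_threshold(inner)
            labels[leaf & (v > t2)] = 2
    return LabelMap(labels)


def predict_labels(
    method: str,
    image: ColorImage,
    background: Background,
    params: FusionParams | None = None,
    seed: int = 0,
) -> LabelMap:
    """Produce a three-class label map with the named method."""
    from .color_gradient import rgb_to_hsv

    params = params or FusionParams()
    if method == "mcge":
        return segment(image, background, params, seed)
    hsv = rgb_to_hsv(image)
    v = hsv.channel(2)
    if method == "exg":
        veg = exg_segment(image).values.astype(bool)
        leaf = _fill_largest(veg)
        labels = np.zeros(v.shape, dtype=np.uint8)
        labels[leaf] = 1
        labels[leaf & ~veg] = 2  # non-green patches inside the leaf
        return LabelMap(labels)
    if method == "otsu":
        _, mask = otsu_segment(v)
        return _bright_split_labels(v, mask.values.astype(bool))
    if method == "iterative":
        t = iterative_threshold(v)
        return _bright_split_labels(v, v > t)
    if method == "kmeans":
        return kmeans_segment(image, k=3, seed=seed)
    if method == "hsv":
        return hsv_threshold_segment(image)
    raise ValueError(f"unknown method '{method}' (choose from {METHODS})")


def run_benchmark(
    scenes: Sequence[ScenePack],
    config: RunConfig | None = None,
) -> dict:
    """Evaluate every configured method on every scene.

    Returns a JSON-serializable report: per (method x background)
    frost- and leaf-class R_ms (mean ± SD) and Dice, totals as the
    unweighted mean across backgrounds, per-level mean FCR against the
    generator truth with the resulting average precision, and the full
    resolved configuration.
    """
    if not scenes:
        raise ValueError("no scenes found")
    config = config or RunConfig()
    report: dict = {
        "config": config.model_dump(),
        "n_scenes": len(scenes),
        "methods": {},
        "skipped": [],
    }
    backgrounds = sorted({s.background for s in scenes}, key=lambda b: b.value)
    levels = [FrostLevel.I, FrostLevel.II, FrostLevel.III]

    for method in config.methods:
        per_bg: dict = {}
        pairs_frost: dict[Background, list[EvalPair]] = {b: [] for b in backgrounds}
        pairs_leaf: dict[Background, list[EvalPair]] = {b: [] for b in backgrounds}
        fcr_by_level: dict[FrostLevel, list[float]] = {lv: [] for lv in levels}
        ref_by_level: dict[FrostLevel, list[float]] = {lv: [] for lv in levels}
        for i, scene in enumerate(scenes):
            try:
                pred = predict_labels(
                    method, scene.image, scene.background, config.fusion, config.seed
                )
            except NoLeafError as exc:
                logger.warning("scene %d skipped by %s: %s", i, method, exc)
                report["skipped"].append({"scene": i, "method": method, "reason": str(exc)})
                continue
            pairs_frost[scene.background].append(EvalPair(pred, scene.truth, "frost"))
            pairs_leaf[scene.background].append(EvalPair(pred, scene.truth, "leaf"))
            try:
                est = frost_coverage_ratio(pred, scene.background)
            except ValueError:
                est = float("nan")
            fcr_by_level[scene.level].append(est)
            ref_by_level[scene.level].append(scene.true_fcr)
            logger.info(
                "%s | %s scene %d: est FCR %.2f (true %.2f)",
                method, scene.background.value, i, est, scene.true_fcr,
            )
        for bg in backgrounds:
            fp = pairs_frost[bg]
            lp = pairs_leaf[bg]
            if not fp:
                per_bg[bg.value] = None
                continue
            per_rates = [mis_segmentation_rate([p]) for p in fp]
            per_bg[bg.value] = {
                "r_ms_frost_mean": float(np.mean(per_rates)),
                "r_ms_frost_sd": float(np.std(per_rates)),
                "r_ms_leaf_mean": mis_segmentation_rate(lp),
                "dice_frost": dice(fp),
                "dice_leaf": dice(lp),
                "n": len(fp),
            }
        cells = [per_bg[bg.value] for bg in backgrounds if per_bg[bg.value]]
        totals = {
            key: float(np.mean([c[key] for c in cells]))
            for key in ("r_ms_frost_mean", "r_ms_leaf_mean", "dice_frost", "dice_leaf")
        } if cells else {}
        level_rows = {}
        est_means, ref_means = [], []
        for lv in levels:
            vals = [x for x in fcr_by_level[lv] if np.isfinite(x)]
            refs = ref_by_level[lv][: len(vals)] if vals else []
            if vals:
                level_rows[lv.value] = {
                    "mean_est_fcr": float(np.mean(vals)),
                    "mean_true_fcr": float(np.mean(ref_by_level[lv])),
                    "n": len(vals),
                }
                est_means.append(float(np.mean(vals)))
                ref_means.append(float(np.mean(ref_by_level[lv])))
        r_a = average_precision(est_means, ref_means) if est_means else None
        report["methods"][method] = {
            "per_background": per_bg,
            "totals": totals,
            "per_level_fcr": level_rows,
            "average_precision": r_a,
        }
    return report


def render_tables(report: dict) -> str:
    """Aligned plain-text tables mirroring the JSON benchmark report."""
    lines = []
    bgs = [b.value for b in Background]
    header = f"{'Method':<10}" + "".join(f"{b:>18}" for b in bgs) + f"{'Total':>18}"
    lines.append("Frost-class mis-segmentation rate R_ms (%) mean ± SD")
    lines.append(header)
    for method, res in report["methods"].items():
        row = f"{method:<10}"
        for b in bgs:
            cell = res["per_background"].get(b)
            row += f"{cell['r_ms_frost_mean']:>10.2f} ± {cell['r_ms_frost_sd']:<5.2f}" if cell else f"{'-':>18}"
        total = res["totals"].get("r_ms_frost_mean")
        row += f"{total:>18.2f}" if total is not None else f"{'-':>18}"
        lines.append(row)
    lines.append("")
    lines.append("Frost-class Dice and coverage precision")
    lines.append(f"{'Method':<10}{'Dice':>8}{'R_a (%)':>10}   mean FCR per level (est/true)")
    for method, res in report["methods"].items():
        d = res["totals"].get("dice_frost")
        ra = res["average_precision"]
        levels = "  ".join(
            f"{lv}: {row['mean_est_fcr']:.1f}/{row['mean_true_fcr']:.1f}"
            for lv, row in res["per_level_fcr"].items()
        )
        lines.append(
            f"{method:<10}{(f'{d:.3f}' if d is not None else '-'):>8}"
            f"{(f'{ra:.2f}' if ra is not None else '-'):>10}   {levels}"
        )
    return "\n".join(lines)
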