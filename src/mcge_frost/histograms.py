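"""Descriptive channel-histogram utilities (inspection only)."""

from __future__ import annotations

import numpy as np

from .color_gradient import ColorImage, ColorSpace, rgb_to_hsv

__all__ = ["channel_histograms", "plot_channel_histograms"]


def channel_histograms(img: ColorImage, space: ColorSpace = ColorSpace.HSV) -> dict[str, np.ndarray]:
    """256-bin counts per channel, in the requested colour space."""
    if space is ColorSpace.HSV and img.space is ColorSpace.RGB:
        img = rgb_to_hsv(img)
    elif img.space is not space:
        raise ValueError(f"cannot derive {space.value} histograms from {img.space.value}")
    names = "HSV" if space is ColorSpace.HSV else "RGB"
    return {
        name: np.bincount(img.pixels[:, :, i].ravel(), minlength=256)
        for i, name in enumerate(names)
    }


def plot_channel_histograms(img: ColorImage, space: ColorSpace = ColorSpace.HSV, ax=None):
    """Line plot of the per-channel histograms; returns the axes."""
    import matplotlib.pyplot as plt

    hists = channel_histograms(img, space)
    if ax is None:
        _, ax = plt.subplots()
    for name, counts in hists.items():
        ax.plot(counts, label=name)
    ax.set_xlabel("level")
    ax.set_ylabel("pixel count")
    ax.legend()
    return ax
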