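"""Shared fixtures: seeded RNGs and the synthetic evaluation suite."""

from __future__ import annotations

import numpy as np
import pytest

from mcge_frost import Background, generate_scene
from mcge_frost.edge_gradient import FusionParams
from mcge_frost.segmentation import segment

#: Coverage targets spanning the three severity strata, ten per background.
SUITE_TARGETS = [5.0, 12.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0, 95.0]
SUITE_SEED = 1


def build_suite(seed: int = SUITE_SEED, size: tuple[int, int] = (256, 256)) -> list:
    """Ten scenes per background with coverage spanning all three levels."""
    rng = np.random.default_rng(seed)
    scenes = []
    for background in Background:
        for target in SUITE_TARGETS:
            scenes.append(
                generate_scene(background, target, size, seed=int(rng.integers(2**31)))
            )
    return scenes


@pytest.fixture(scope="session")
def suite():
    """The 30-scene fixed-seed evaluation suite (10 per background)."""
    return build_suite()


@pytest.fixture(scope="session")
def suite_segmentations(suite):
    """Full-pipeline label maps for every suite scene, default parameters."""
    params = FusionParams()
    return [segment(s.image, s.background, params) for s in suite]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
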