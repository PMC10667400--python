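from __future__ import annotations

import numpy as np
import pytest

from radrepro.preprocess import DiscretizedROI
from radrepro.synthetic import SimulationConfig, generate_cohort

SPACING = (0.5, 0.5, 3.0)


def random_roi(rng: np.random.Generator, max_ng: int = 8, max_side: int = 7):
    """Small random ROI: continuous volume, random blobby mask, levels."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    volume = rng.normal(400.0, 120.0, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(int(s) // 2 for s in shape)] = True
    ng = int(rng.integers(2, max_ng + 1))
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    disc = DiscretizedROI(
        levels=levels,
        mask=mask,
        n_levels=ng,
        x_min=float(volume[mask].min()),
        x_max=float(volume[mask].max()),
        discretization="FBN",
        binning=ng,
    )
    return volume, mask, disc


@pytest.fixture(scope="session")
def random_rois():
    """22 random small ROIs shared across oracle tests."""
    rng = np.random.default_rng(20240917)
    return [random_roi(rng) for _ in range(22)]


@pytest.fixture(scope="session")
def small_cohort():
    """Six paired lesions with modest ROIs; session-cached."""
    config = SimulationConfig(
        n_patients=4,
        n_lesions=6,
        grid_shape=(48, 48, 12),
        lesion_radius_range=(3.0, 5.0),
        seed=11,
    )
    return generate_cohort(config), config
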