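from __future__ import annotations

import numpy as np
import pytest

from radstab.discretize import DiscretizedROI
from radstab.imaging import VolumeWithMask
from radstab.synthetic import LesionSpec, make_phantom

DEFAULT_SPACING = (1.0, 1.0, 1.0)


def disc_from_levels(levels, ng: int | None = None, spacing=DEFAULT_SPACING) -> DiscretizedROI:
    """Wrap an explicit level grid (0 = out of mask) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    mask = (levels > 0).astype(np.uint8)
    ng = ng or int(levels.max())
    edges = np.linspace(0.0, float(ng), ng + 1)
    return DiscretizedROI(levels, ng, mask, spacing, edges, degenerate=False)


@pytest.fixture
def phantom() -> VolumeWithMask:
    """A deterministic textured-lesion phantom with a ~230-voxel ROI."""
    spec = LesionSpec(
        center=(32.0, 32.0, 4.0), radius_mm=16.0, contrast=80.0,
        texture_amplitude=20.0, texture_correlation_length_mm=5.0,
    )
    return make_phantom(spec, (64, 64, 8), (3.28, 3.28, 7.0), seed=7)


@pytest.fixture
def constant_phantom() -> VolumeWithMask:
    """Flat image: every voxel (in-mask and out) shares one value."""
    img = np.full((16, 16, 3), 50.0)
    mask = np.zeros((16, 16, 3), dtype=np.uint8)
    mask[4:12, 4:12, 1] = 1
    return VolumeWithMask(img, (1.0, 1.0, 5.0), mask)
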