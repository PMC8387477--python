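"""Fixed-bin-number gray-level discretization of ROI intensities.

All texture matrices consume the integer levels produced here.  A fixed bin
NUMBER (rather than a fixed bin width) is used because paired acquisitions
have different intensity scales; the mapping is invariant under positive
affine rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radstab.imaging import VolumeWithMask

DEFAULT_NG = 32


@dataclass
class DiscretizedROI:
    """Integer gray levels in ``1..Ng`` over the in-mask voxels.

    ``levels`` is a full grid; out-of-mask voxels hold 0 and must never be
    consumed by feature code.  ``degenerate`` is set when the ROI is constant
    (max == min), in which case all in-mask levels are 1.
    """

    levels: np.ndarray  # int grid, 0 outside mask
    ng: int
    mask: np.ndarray
    spacing: tuple[float, float, float]
    bin_edges: np.ndarray
    degenerate: bool = False

    @property
    def roi_levels(self) -> np.ndarray:
        """1D array of the in-mask levels."""
        return self.levels[self.mask != 0]


def discretize_fixed_bins(volume: VolumeWithMask, ng: int = DEFAULT_NG) -> DiscretizedROI:
    """Map in-mask intensities to levels ``1..ng`` with equal-width bins.

    ``level(v) = min(ng, floor(ng * (x - min) / (max - min)) + 1)`` computed
    over in-mask voxels only.  A constant ROI maps everything to level 1 and
    is flagged degenerate.
    """
    if ng < 2:
        raise ValueError(f"need at least 2 gray levels, got {ng}")
    mask = volume.mask != 0
    if not mask.any():
        raise ValueError("cannot discretize an empty mask")
    values = volume.intensities[mask]
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        edges = np.linspace(lo, lo + 1.0, ng + 1)  # placeholder span for a flat ROI
        return DiscretizedROI(levels, ng, mask.astype(np.uint8), volume.spacing, edges, True)
    scaled = np.floor(ng * (values - lo) / (hi - lo)).astype(np.int32) + 1
    levels[mask] = np.minimum(scaled, ng)
    edges = np.linspace(lo, hi, ng + 1)
    return DiscretizedROI(levels, ng, mask.astype(np.uint8), volume.spacing, edges, False)
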