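"""Gray-level texture matrices: GLCM, GLRLM, GLSZM and the NGTDM table.

All matrices are built per slice with in-plane offsets only and pooled
(count-summed) across slices and directions before any normalisation.
Through-plane offsets are deliberately excluded: thick, gapped slices make
3D co-occurrence physically inhomogeneous.

Level grids come from :class:`radstab.discretize.DiscretizedROI`: integers
``1..Ng`` inside the mask, 0 outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from radstab.discretize import DiscretizedROI

#: distance-1 in-plane offsets (dx, dy): 0°, 90°, 45°, 135°
IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))

_EIGHT_CONN = np.ones((3, 3), dtype=np.uint8)


@dataclass
class TextureMatrix:
    """A pooled texture-count array plus the bookkeeping features need."""

    kind: str  # "glcm" | "glrlm" | "glszm"
    counts: np.ndarray  # integer counts (pre-normalisation)
    ng: int
    n_voxels: int  # in-mask voxels of the source ROI
    n_directions: int = 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            raise ValueError(f"empty {self.kind} matrix: no valid pairs/runs/zones")
        return self.counts / tot


def _masked_slices(disc: DiscretizedROI):
    for z in range(disc.levels.shape[2]):
        sl = disc.levels[:, :, z]
        if (sl > 0).any():
            yield sl


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(
    disc: DiscretizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int], ...] = IN_PLANE_DIRECTIONS,
) -> TextureMatrix:
    """Symmetric co-occurrence counts pooled over slices and directions.

    For each slice and offset ``(dx, dy) * distance``, every ordered pair of
    in-mask voxels contributes one count; the transpose is added so the
    matrix is symmetric, then all counts are summed before normalisation.
    """
    ng = disc.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for sl in _masked_slices(disc):
        nx, ny = sl.shape
        for dx, dy in directions:
            ox, oy = dx * distance, dy * distance
            x0, x1 = max(0, -ox), min(nx, nx - ox)
            y0, y1 = max(0, -oy), min(ny, ny - oy)
            a = sl[x0:x1, y0:y1]
            b = sl[x0 + ox:x1 + ox, y0 + oy:y1 + oy]
            valid = (a > 0) & (b > 0)
            if valid.any():
                np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    counts = counts + counts.T
    return TextureMatrix("glcm", counts, ng, int(disc.mask.sum()), len(directions))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _run_lengths(line: np.ndarray):
    """Yield (level, length) for maximal constant nonzero segments of a 1D line."""
    n = line.size
    i = 0
    while i < n:
        v = line[i]
        if v == 0:
            i += 1
            continue
        j = i + 1
        while j < n and line[j] == v:
            j += 1
        yield int(v), j - i
        i = j


def _slice_lines(sl: np.ndarray, direction: tuple[int, int]):
    """1D scan lines of a slice along an in-plane direction."""
    dx, dy = direction
    if (dx, dy) == (1, 0):
        yield from sl.T  # along x for each y
    elif (dx, dy) == (0, 1):
        yield from sl  # along y for each x
    elif (dx, dy) == (1, 1):
        nx, ny = sl.shape
        for off in range(-(nx - 1), ny):
            yield np.diagonal(sl, offset=off)
    elif (dx, dy) == (1, -1):
        yield from _slice_lines(sl[:, ::-1], (1, 1))
    else:
        raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(
    disc: DiscretizedROI,
    directions: tuple[tuple[int, int], ...] = IN_PLANE_DIRECTIONS,
) -> TextureMatrix:
    """Run-length counts ``R[level-1, length-1]`` pooled over slices/directions."""
    ng = disc.ng
    max_len = max(disc.levels.shape[0], disc.levels.shape[1])
    counts = np.zeros((ng, max_len), dtype=np.int64)
    for sl in _masked_slices(disc):
        for d in directions:
            for line in _slice_lines(sl, d):
                for level, length in _run_lengths(np.asarray(line)):
                    counts[level - 1, length - 1] += 1
    used = np.nonzero(counts.any(axis=0))[0]
    if used.size:
        counts = counts[:, : used[-1] + 1]
    return TextureMatrix("glrlm", counts, ng, int(disc.mask.sum()), len(directions))


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(disc: DiscretizedROI) -> TextureMatrix:
    """Size-zone counts ``Z[level-1, size-1]``; zones are in-plane 8-connected
    components of equal level, pooled over slices."""
    ng = disc.ng
    sizes_by_level: dict[int, list[int]] = {}
    max_size = 1
    for sl in _masked_slices(disc):
        for level in np.unique(sl[sl > 0]):
            labels, n = ndimage.label(sl == level, structure=_EIGHT_CONN)
            if n == 0:
                continue
            zone_sizes = np.bincount(labels.ravel())[1:]
            sizes_by_level.setdefault(int(level), []).extend(int(s) for s in zone_sizes)
            max_size = max(max_size, int(zone_sizes.max()))
    counts = np.zeros((ng, max_size), dtype=np.int64)
    for level, sizes in sizes_by_level.items():
        for s in sizes:
            counts[level - 1, s - 1] += 1
    return TextureMatrix("glszm", counts, ng, int(disc.mask.sum()), 1)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

@dataclass
class NGTDMTable:
    """Per-level occurrence counts ``n_i`` and summed absolute deviations
    ``s_i`` of each voxel's level from its in-mask 8-neighbourhood mean.

    Only voxels with at least one in-mask in-plane neighbour participate;
    ``n_total`` is their count.
    """

    n: np.ndarray  # shape (ng,)
    s: np.ndarray  # shape (ng,)
    ng: int

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    def probabilities(self) -> np.ndarray:
        tot = self.n_total
        if tot == 0:
            raise ValueError("NGTDM: no voxel has an in-mask in-plane neighbour")
        return self.n / tot


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def ngtdm_table(disc: DiscretizedROI) -> NGTDMTable:
    ng = disc.ng
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=np.float64)
    for sl in _masked_slices(disc):
        inmask = (sl > 0).astype(np.float64)
        lvl = sl.astype(np.float64)
        neigh_sum = ndimage.correlate(lvl * inmask, _NEIGH_KERNEL, mode="constant")
        neigh_cnt = ndimage.correlate(inmask, _NEIGH_KERNEL, mode="constant")
        valid = (sl > 0) & (neigh_cnt > 0)
        if not valid.any():
            continue
        dev = np.abs(lvl[valid] - neigh_sum[valid] / neigh_cnt[valid])
        levels = sl[valid] - 1
        np.add.at(n, levels, 1)
        np.add.at(s, levels, dev)
    return NGTDMTable(n, s, ng)
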