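"""Volume/mask data model, NIfTI I/O and ROI-mask algebra.

Grids are indexed ``(x, y, slice)`` with 0-based voxel indices; the physical
extent along each axis is ``n * spacing``.  Inputs are assumed co-aligned in
physical space — only grid resampling is performed here (nearest-neighbour for
masks so binarity is preserved, linear for intensities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Sequence label used as the reference acquisition throughout.
REFERENCE_SEQUENCE = "conventional"

#: Minimum foreground voxels an ROI needs before feature extraction is allowed.
MIN_ROI_VOXELS = 10


class MaskKind(str, Enum):
    """Whether an ROI is a sequence's own mask or the paired intersection."""

    WHOLE = "whole"
    INTERSECTION = "intersection"


@dataclass
class VolumeWithMask:
    """A 3D intensity grid plus voxel spacing plus a binary ROI mask.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar image values in arbitrary units.
    spacing : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in millimetres, all strictly positive.
    mask : ndarray of uint8, same shape
        Binary ROI; may be empty at construction but extraction requires
        at least :data:`MIN_ROI_VOXELS` foreground voxels.
    meta : dict
        Free-form provenance: sequence label, subject id, lesion class, group.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.intensities.ndim}D shape "
                f"{self.intensities.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.mask is None:
            self.mask = np.zeros(self.intensities.shape, dtype=np.uint8)
        else:
            self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
            if self.mask.shape != self.intensities.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != volume shape {self.intensities.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def roi_voxels(self) -> int:
        return int(self.mask.sum())

    def with_mask(self, mask: np.ndarray) -> "VolumeWithMask":
        return replace(self, mask=(np.asarray(mask) != 0).astype(np.uint8))

    def require_roi(self) -> None:
        """Raise if the ROI is too small for feature extraction."""
        n = self.roi_voxels
        if n < MIN_ROI_VOXELS:
            raise ROITooSmallError(
                f"ROI has {n} foreground voxels; minimum is {MIN_ROI_VOXELS}"
            )


class ROITooSmallError(ValueError):
    """ROI below the minimum voxel count for texture extraction."""


def write_volume(vol: VolumeWithMask, volume_path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write intensities (float64) and, optionally, the mask (uint8) as NIfTI."""
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float64), affine), str(volume_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(mask_path))


def read_volume(path: str | Path, meta: Mapping | None = None) -> VolumeWithMask:
    """Read a 3D NIfTI image into a :class:`VolumeWithMask` (mask left empty).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the image is not 3D or the header is unreadable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # corrupt header / payload
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    while data.ndim > 3 and data.shape[-1] == 1:  # drop trailing singleton dims only
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume at {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return VolumeWithMask(
        intensities=data,
        spacing=tuple(float(z) for z in zooms),
        meta=dict(meta or {}),
    )


def read_mask(path: str | Path, reference: VolumeWithMask) -> np.ndarray:
    """Read a binary ROI mask and align it to *reference*'s grid.

    Any nonzero voxel counts as foreground.  When the mask lives on a
    different grid with the same physical extent it is resampled to the
    reference grid by nearest neighbour.

    Raises
    ------
    ValueError
        If the physical extents disagree by more than half a voxel.
    """
    src = read_volume(path)
    binary = (src.intensities != 0).astype(np.uint8)
    if src.shape == reference.shape and np.allclose(src.spacing, reference.spacing):
        return binary
    src_extent = np.array(src.shape) * np.array(src.spacing)
    ref_extent = np.array(reference.shape) * np.array(reference.spacing)
    tol = np.maximum(np.array(src.spacing), np.array(reference.spacing)) / 2.0
    if np.any(np.abs(src_extent - ref_extent) > tol):
        raise ValueError(
            f"incompatible physical extents: mask {path} covers "
            f"{tuple(src_extent)} mm on grid {src.shape}, reference covers "
            f"{tuple(ref_extent)} mm on grid {reference.shape}"
        )
    return resample_mask(binary, src.spacing, reference.shape, reference.spacing)


def _target_coords(src_shape, src_spacing, tgt_shape, tgt_spacing) -> list[np.ndarray]:
    """Source-index coordinates of each target voxel centre (shared origin)."""
    axes = []
    for n_t, d_t, d_s in zip(tgt_shape, tgt_spacing, src_spacing):
        centers = (np.arange(n_t) + 0.5) * d_t  # physical position, mm
        axes.append(centers / d_s - 0.5)  # fractional source index
    return np.meshgrid(*axes, indexing="ij")


def resample_mask(mask, src_spacing, tgt_shape, tgt_spacing) -> np.ndarray:
    """Nearest-neighbour resample of a binary grid onto a target grid."""
    coords = _target_coords(mask.shape, src_spacing, tgt_shape, tgt_spacing)
    out = ndimage.map_coordinates(
        mask.astype(np.uint8), np.array(coords), order=0, mode="nearest"
    )
    return out.astype(np.uint8)


def resample_intensities(data, src_spacing, tgt_shape, tgt_spacing) -> np.ndarray:
    """Trilinear resample of an intensity grid onto a target grid."""
    coords = _target_coords(data.shape, src_spacing, tgt_shape, tgt_spacing)
    return ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64), np.array(coords), order=1, mode="nearest"
    )


def intersect_masks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise AND of two binary grids on the same grid."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return ((a != 0) & (b != 0)).astype(np.uint8)


# ---------------------------------------------------------------------------
# Mask-role enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionTask:
    """One feature-extraction job: which image, which mask.

    ``pairing`` is ``None`` for whole masks; for intersection masks it names
    the fast sequence whose mask was intersected with the conventional one
    (the intersection is applied on the image named by ``sequence``).
    """

    subject_id: str
    group: str
    lesion_class: str
    sequence: str
    mask_kind: MaskKind
    pairing: str | None = None

    @property
    def role(self) -> tuple:
        """The (group, sequence, mask kind, pairing) role this task fills."""
        return (self.group, self.sequence, self.mask_kind.value, self.pairing)


@dataclass
class SubjectRecord:
    """A subject's acquisitions: sequence label -> (volume path, mask path)."""

    subject_id: str
    group: str
    lesion_class: str
    sequences: dict[str, tuple[str, str]] = field(default_factory=dict)


def enumerate_mask_set(cohort: Sequence[SubjectRecord]) -> list[ExtractionTask]:
    """Expand a cohort into per-subject extraction tasks over all mask roles.

    Per group with a conventional reference and two fast sequences this yields
    3 whole-mask roles plus 4 intersection-mask roles (each conventional–fast
    intersection applied on both members of the pair) — 7 roles per group, 14
    across a two-group cohort.  Subjects missing the conventional reference
    are skipped with a warning.
    """
    tasks: list[ExtractionTask] = []
    for rec in cohort:
        if REFERENCE_SEQUENCE not in rec.sequences:
            logger.warning(
                "subject %s has no %s reference; skipping", rec.subject_id, REFERENCE_SEQUENCE
            )
            continue
        fast = sorted(s for s in rec.sequences if s != REFERENCE_SEQUENCE)
        for seq in [REFERENCE_SEQUENCE, *fast]:
            tasks.append(
                ExtractionTask(rec.subject_id, rec.group, rec.lesion_class, seq, MaskKind.WHOLE)
            )
        for f in fast:
            for seq in (REFERENCE_SEQUENCE, f):
                tasks.append(
                    ExtractionTask(
                        rec.subject_id, rec.group, rec.lesion_class, seq,
                        MaskKind.INTERSECTION, pairing=f,
                    )
                )
    return tasks


def distinct_roles(tasks: Iterable[ExtractionTask]) -> set[tuple]:
    return {t.role for t in tasks}
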