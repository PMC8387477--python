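"""Synthetic paired-acquisition cohorts.

Generates textured hyperintense-lesion phantoms, degrades them through
parameterized "fast acquisition" profiles (acquisition matrix, in-plane blur,
additive noise, imperfect mask transfer), and simulates feature-level paired
draws with a known population concordance.  All randomness flows from explicit
seeds; reruns are bit-reproducible.

Acquisition matrices follow the study protocol (conventional 256x218,
EPI 128x128, ETL 192x192, TR 256x256), optionally divided by a demo scale
factor so desk-scale runs stay fast.  Noise and blur magnitudes are free
simulator knobs with documented defaults, not protocol values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from radstab.imaging import (
    MIN_ROI_VOXELS,
    VolumeWithMask,
    resample_intensities,
    resample_mask,
    write_volume,
)

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: protocol acquisition matrices (nx, ny)
PROTOCOL_MATRICES: dict[str, tuple[int, int]] = {
    "conventional": (256, 218),
    "EPI": (128, 128),
    "ETL": (192, 192),
    "TR": (256, 256),
}


@dataclass(frozen=True)
class AcquisitionProfile:
    """Degradation parameters one synthetic "sequence" applies.

    ``noise_sigma`` is expressed as a fraction of the lesion-background
    contrast; ``blur_fwhm`` is the in-plane Gaussian blur in mm;
    ``mask_flip_prob`` is the per-boundary-voxel probability of a one-voxel
    erosion/dilation flip of the transferred ROI mask.
    """

    name: str
    matrix: tuple[int, int]
    noise_sigma: float = 0.0
    blur_fwhm: float = 0.0
    seed_offset: int = 0
    mask_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if min(self.matrix) < 16:
            raise ValueError(f"acquisition matrix components must be >= 16, got {self.matrix}")
        if self.noise_sigma < 0 or self.blur_fwhm < 0:
            raise ValueError("noise_sigma and blur_fwhm must be non-negative")
        if not 0 <= self.mask_flip_prob <= 1:
            raise ValueError("mask_flip_prob must be in [0, 1]")


def identity_profile(name: str, shape: tuple[int, ...], seed_offset: int = 0) -> AcquisitionProfile:
    """A profile that reproduces the truth grid exactly (null experiment)."""
    return AcquisitionProfile(name, (shape[0], shape[1]), 0.0, 0.0, seed_offset, 0.0)


def demo_profiles(scale: int = 4, noise_level: float = 1.0) -> dict[str, AcquisitionProfile]:
    """Protocol-matrix profiles divided by ``scale``, with default noise/blur knobs."""

    def mtx(name: str) -> tuple[int, int]:
        nx, ny = PROTOCOL_MATRICES[name]
        return (nx // scale, ny // scale)

    return {
        "conventional": AcquisitionProfile("conventional", mtx("conventional"), 0.01 * noise_level, 0.0, 0, 0.0),
        "EPI": AcquisitionProfile("EPI", mtx("EPI"), 0.05 * noise_level, 1.5, 1, 0.15),
        "ETL": AcquisitionProfile("ETL", mtx("ETL"), 0.15 * noise_level, 1.5, 2, 0.15),
        "TR": AcquisitionProfile("TR", mtx("TR"), 0.05 * noise_level, 0.0, 3, 0.15),
    }


@dataclass
class LesionSpec:
    """Geometry and texture of one synthetic hyperintense lesion."""

    center: tuple[float, float, float]  # voxel coordinates
    radius_mm: float
    contrast: float  # lesion-minus-background mean intensity, > 0
    texture_amplitude: float = 0.0
    texture_correlation_length_mm: float = 5.0
    background: float = 100.0
    background_amplitude: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive (hyperintense lesion)")


def _correlated_field(shape, spacing, corr_len_mm, rng) -> np.ndarray:
    """Zero-mean, unit-std Gaussian field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma = [max(corr_len_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_phantom(
    spec: LesionSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int,
) -> VolumeWithMask:
    """Textured hyperintense sphere on a smoothly varying darker background.

    The mask contains exactly the voxels whose centre lies within
    ``radius_mm`` of the lesion centre (physical distance).  Deterministic
    given ``seed``.
    """
    for c, n, d in zip(spec.center, shape, spacing):
        if c * d - spec.radius_mm < 0 or c * d + spec.radius_mm > n * d:
            raise ValueError(
                f"lesion (centre {spec.center}, radius {spec.radius_mm} mm) "
                f"does not fit inside grid {shape} at spacing {spacing}"
            )
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    dist2 = sum(((g - c) * d) ** 2 for g, c, d in zip(grids, spec.center, spacing))
    mask = (dist2 <= spec.radius_mm**2).astype(np.uint8)

    img = np.full(shape, spec.background, dtype=np.float64)
    img += spec.background_amplitude * _correlated_field(shape, spacing, 3 * spec.texture_correlation_length_mm, rng)
    lesion_tex = _correlated_field(shape, spacing, spec.texture_correlation_length_mm, rng)
    img[mask != 0] += spec.contrast + spec.texture_amplitude * lesion_tex[mask != 0]
    return VolumeWithMask(img, spacing, mask, meta={"contrast": spec.contrast})


_INPLANE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_STRUCT[:, :, 1] = True


def _jitter_mask(mask: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded one-voxel boundary erosion/dilation; never shrinks the ROI
    below the extraction minimum."""
    m = mask != 0
    outer = ndimage.binary_dilation(m, structure=_INPLANE_STRUCT) & ~m
    inner = m & ~ndimage.binary_erosion(m, structure=_INPLANE_STRUCT)
    add = outer & (rng.random(mask.shape) < prob)
    drop = inner & (rng.random(mask.shape) < prob)
    out = (m | add) & ~drop
    if out.sum() < max(MIN_ROI_VOXELS, 1):
        out = m | add
    return out.astype(np.uint8)


def degrade_acquisition(
    truth: VolumeWithMask, profile: AcquisitionProfile, seed: int
) -> VolumeWithMask:
    """Emulate one acquisition: blur, down-sample, add noise, transfer mask.

    Pipeline: in-plane Gaussian blur (``blur_fwhm``) -> linear down-sampling
    to ``profile.matrix`` (same physical extent) -> additive Gaussian noise
    scaled by the lesion contrast -> nearest-neighbour mask transfer with
    seeded one-voxel boundary jitter.
    """
    nx, ny, nz = truth.shape
    if profile.matrix[0] > nx or profile.matrix[1] > ny:
        raise ValueError(
            f"profile matrix {profile.matrix} exceeds truth in-plane grid {(nx, ny)}"
        )
    rng = np.random.default_rng(seed + profile.seed_offset)

    data = truth.intensities
    if profile.blur_fwhm > 0:
        sig = profile.blur_fwhm / _FWHM_TO_SIGMA
        data = ndimage.gaussian_filter(
            data, sigma=(sig / truth.spacing[0], sig / truth.spacing[1], 0.0), mode="reflect"
        )

    tgt_shape = (profile.matrix[0], profile.matrix[1], nz)
    extent = np.array(truth.shape) * np.array(truth.spacing)
    tgt_spacing = tuple(float(e / n) for e, n in zip(extent, tgt_shape))
    if tgt_shape != truth.shape:
        data = resample_intensities(data, truth.spacing, tgt_shape, tgt_spacing)
        mask = resample_mask(truth.mask, truth.spacing, tgt_shape, tgt_spacing)
    else:
        data = data.copy()
        mask = truth.mask.copy()

    if profile.noise_sigma > 0:
        contrast = float(truth.meta.get("contrast", 0.0))
        if contrast <= 0:
            inm = truth.mask != 0
            contrast = abs(float(truth.intensities[inm].mean() - truth.intensities[~inm].mean()))
        data = data + rng.normal(0.0, profile.noise_sigma * contrast, size=data.shape)

    if profile.mask_flip_prob > 0:
        mask = _jitter_mask(mask, profile.mask_flip_prob, rng)

    meta = dict(truth.meta)
    meta["sequence"] = profile.name
    return VolumeWithMask(data, tgt_spacing, mask, meta=meta)


# ---------------------------------------------------------------------------
# Feature-level simulation (parameter recovery for the concordance estimator)
# ---------------------------------------------------------------------------

def simulate_feature_pairs(
    n_subjects: int,
    n_features: int,
    target_ccc: float | np.ndarray,
    seed: int,
    feature_names: list[str] | None = None,
) -> "pd.DataFrame":
    """Paired draws whose population concordance equals ``target_ccc``.

    Each feature's pairs come from a bivariate normal with equal means and
    unit variances and correlation ``target_ccc`` — for which Lin's
    coefficient equals the correlation.  ``target_ccc == 1`` duplicates the
    draw exactly.  Returns a long-form frame with columns
    ``feature_name, subject_id, x, y``.
    """
    if n_subjects < 3:
        raise ValueError(f"need at least 3 subjects, got {n_subjects}")
    rho = np.broadcast_to(np.asarray(target_ccc, dtype=np.float64), (n_features,)).copy()
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("target_ccc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((n_features, n_subjects))
    z2 = rng.standard_normal((n_features, n_subjects))
    y = rho[:, None] * z1 + np.sqrt(1.0 - rho[:, None] ** 2) * z2
    names = feature_names or [f"f{i:04d}" for i in range(n_features)]
    frames = []
    for k, name in enumerate(names):
        frames.append(
            pd.DataFrame(
                {
                    "feature_name": name,
                    "subject_id": [f"s{j:04d}" for j in range(n_subjects)],
                    "x": z1[k],
                    "y": y[k],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Demo cohort on disk
# ---------------------------------------------------------------------------

GROUP_SEQUENCES = {
    "first": ("conventional", "EPI", "ETL"),
    "second": ("conventional", "ETL", "TR"),
}

DEFAULT_SHAPE = (64, 64, 8)
DEFAULT_SPACING = (210.0 / 64, 210.0 / 64, 7.0)  # 210 mm FOV; 5 mm slices + 2 mm gap


@dataclass
class CohortConfig:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    scale: int = 4  # divisor applied to the protocol matrices
    noise_level: float = 1.0
    profiles: dict[str, AcquisitionProfile] | None = None
    lesion_classes: tuple[str, ...] = ("acute", "chronic")


def build_demo_cohort(
    n_per_group: int,
    seed: int,
    outdir: str | Path,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Write a two-group paired-acquisition cohort to ``outdir``.

    Group "first" subjects get conventional+EPI+ETL renditions; group
    "second" get conventional+ETL+TR.  Lesion classes alternate between
    acute and chronic within each group.  Returns (and writes as
    ``manifest.csv``) one row per (subject, sequence) with the NIfTI paths.
    """
    cfg = config or CohortConfig()
    profiles = cfg.profiles or demo_profiles(cfg.scale, cfg.noise_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    subj_idx = 0
    for group in ("first", "second"):
        for _ in range(n_per_group):
            subject_id = f"sub-{subj_idx:03d}"
            lesion_class = cfg.lesion_classes[subj_idx % len(cfg.lesion_classes)]
            spec = LesionSpec(
                center=tuple(
                    n / 2 + rng.uniform(-2, 2) for n in cfg.shape[:2]
                ) + (cfg.shape[2] / 2,),
                radius_mm=float(rng.uniform(14.0, 20.0)),
                contrast=float(rng.uniform(60.0, 100.0)),
                texture_amplitude=float(rng.uniform(15.0, 30.0)),
                texture_correlation_length_mm=float(rng.uniform(4.0, 8.0)),
            )
            truth = make_phantom(spec, cfg.shape, cfg.spacing, seed=seed + 1000 + subj_idx)
            truth.meta.update(subject_id=subject_id, group=group, lesion_class=lesion_class)
            for seq in GROUP_SEQUENCES[group]:
                rendition = degrade_acquisition(
                    truth, profiles[seq], seed=seed + 5000 + 100 * subj_idx
                )
                vol_path = outdir / f"{subject_id}_{seq}_vol.nii"
                mask_path = outdir / f"{subject_id}_{seq}_mask.nii"
                write_volume(rendition, vol_path, mask_path)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "lesion_class": lesion_class,
                        "sequence": seq,
                        "volume_path": vol_path.name,
                        "mask_path": mask_path.name,
                    }
                )
            subj_idx += 1

    manifest = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "lesion_class", "sequence", "volume_path", "mask_path"],
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
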