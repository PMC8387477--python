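"""Rotation-invariant uniform local binary pattern (P=8, R=1) summaries.

Codes are computed per slice on the (raw or subband) intensities; only
in-mask voxels with a full in-plane 8-neighbourhood inside the grid
contribute to the 10-bin code histogram.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.feature import local_binary_pattern

P_POINTS = 8
RADIUS = 1
N_BINS = P_POINTS + 2  # rotation-invariant uniform codes 0..9


def lbp_code_histogram(intensities: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """10-bin probability histogram of LBP codes over interior in-mask voxels."""
    codes: list[np.ndarray] = []
    nx, ny, nz = intensities.shape
    for z in range(nz):
        msk = mask[:, :, z] != 0
        interior = np.zeros_like(msk)
        interior[1:-1, 1:-1] = True
        sel = msk & interior
        if not sel.any():
            continue
        with warnings.catch_warnings():
            # float input is intentional: raw/subband intensities, exact ties are unlikely
            warnings.simplefilter("ignore", UserWarning)
            lbp = local_binary_pattern(
                intensities[:, :, z].astype(np.float64), P_POINTS, RADIUS, "uniform"
            )
        codes.append(lbp[sel])
    if not codes:
        raise ValueError("LBP: no in-mask voxel has a full in-plane 8-neighbourhood")
    allcodes = np.concatenate(codes).astype(np.intp)
    hist = np.bincount(allcodes, minlength=N_BINS).astype(np.float64)
    return hist / hist.sum()


def lbp_features(intensities: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    p = lbp_code_histogram(intensities, mask)
    occ = p > 0
    codes = np.arange(N_BINS, dtype=np.float64)
    mean = float(np.sum(codes * p))
    return {
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p[occ] * np.log2(p[occ]))),
        "mean": mean,
        "variance": float(np.sum((codes - mean) ** 2 * p)),
        # codes 0..P are uniform patterns; code P+1 pools all non-uniform ones
        "uniform_fraction": float(p[: P_POINTS + 1].sum()),
    }
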