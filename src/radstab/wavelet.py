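"""Two-level undecimated (à trous) 2D wavelet decomposition, per slice.

Produces 8 subbands — level-1 {LL, LH, HL, HH} and level-2 {LL2, LH2, HL2,
HH2} computed from the level-1 LL band — all on the source grid, so the
unmodified ROI mask applies to every subband.  Haar filters by default;
boundaries are handled symmetrically.  The transform is linear and commutes
with in-plane translation (up to the shared boundary region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from radstab.catalog import SUBBAND_NAMES

_SQRT2 = np.sqrt(2.0)

#: mother wavelets: name -> (lowpass, highpass) analysis filters
FILTER_BANKS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "haar": (np.array([1.0, 1.0]) / _SQRT2, np.array([1.0, -1.0]) / _SQRT2),
}


@dataclass
class SubbandSet:
    """The 8 named filtered volumes, each the same shape as the source."""

    subbands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.subbands) != set(SUBBAND_NAMES):
            raise ValueError(f"expected subbands {SUBBAND_NAMES}, got {sorted(self.subbands)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.subbands[name]


def _atrous(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert ``2**(level-1) - 1`` zeros between taps (algorithme à trous)."""
    if level == 1:
        return filt
    holes = 2 ** (level - 1)
    out = np.zeros((len(filt) - 1) * holes + 1)
    out[::holes] = filt
    return out


def _filter2d(data: np.ndarray, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    """Separable filtering along the two in-plane axes of an (nx, ny, nz) stack."""
    out = ndimage.correlate1d(data, fx, axis=0, mode="reflect", origin=-(len(fx) // 2))
    out = ndimage.correlate1d(out, fy, axis=1, mode="reflect", origin=-(len(fy) // 2))
    return out


def wavelet_decompose(intensities: np.ndarray, family: str = "haar") -> SubbandSet:
    """Decompose a 3D stack slice-wise into the 8 undecimated subbands."""
    data = np.asarray(intensities, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got {data.ndim}D")
    if min(data.shape[0], data.shape[1]) < 8:
        raise ValueError(f"in-plane dims must be >= 8, got {data.shape[:2]}")
    if family not in FILTER_BANKS:
        raise NotImplementedError(f"unknown wavelet family {family!r}; available: {list(FILTER_BANKS)}")
    lo, hi = FILTER_BANKS[family]

    out: dict[str, np.ndarray] = {}
    out["LL"] = _filter2d(data, lo, lo)
    out["LH"] = _filter2d(data, lo, hi)
    out["HL"] = _filter2d(data, hi, lo)
    out["HH"] = _filter2d(data, hi, hi)
    lo2, hi2 = _atrous(lo, 2), _atrous(hi, 2)
    ll = out["LL"]
    out["LL2"] = _filter2d(ll, lo2, lo2)
    out["LH2"] = _filter2d(ll, lo2, hi2)
    out["HL2"] = _filter2d(ll, hi2, lo2)
    out["HH2"] = _filter2d(ll, hi2, hi2)
    return SubbandSet(out)
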