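"""The 13 gray-level size-zone (GLSZM) statistics."""

from __future__ import annotations

import numpy as np

from radstab.features.matrices import TextureMatrix


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    z = m.counts.astype(np.float64)
    n_zones = z.sum()
    if n_zones == 0:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, z.shape[0] + 1)[:, None]  # gray level
    s = np.arange(1, z.shape[1] + 1)[None, :]  # zone size
    p = z / n_zones
    mu_i = float(np.sum(i * p))
    mu_s = float(np.sum(s * p))
    return {
        "sae": float(np.sum(z / s**2) / n_zones),
        "lae": float(np.sum(z * s**2) / n_zones),
        "gln": float(np.sum(z.sum(axis=1) ** 2) / n_zones),
        "zsn": float(np.sum(z.sum(axis=0) ** 2) / n_zones),
        "zp": float(n_zones / m.n_voxels),
        "lgze": float(np.sum(z / i**2) / n_zones),
        "hgze": float(np.sum(z * i**2) / n_zones),
        "salge": float(np.sum(z / (i**2 * s**2)) / n_zones),
        "sahge": float(np.sum(z * i**2 / s**2) / n_zones),
        "lalge": float(np.sum(z * s**2 / i**2) / n_zones),
        "lahge": float(np.sum(z * i**2 * s**2) / n_zones),
        "glv": float(np.sum((i - mu_i) ** 2 * p)),
        "zsv": float(np.sum((s - mu_s) ** 2 * p)),
    }
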