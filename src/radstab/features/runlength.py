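"""The 11 gray-level run-length (GLRLM) statistics."""

from __future__ import annotations

import numpy as np

from radstab.features.matrices import TextureMatrix


def glrlm_features(m: TextureMatrix) -> dict[str, float]:
    r = m.counts.astype(np.float64)
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, r.shape[0] + 1)[:, None]  # gray level
    l = np.arange(1, r.shape[1] + 1)[None, :]  # run length
    n_p = m.n_voxels * m.n_directions  # each voxel belongs to one run per direction
    return {
        "sre": float(np.sum(r / l**2) / n_runs),
        "lre": float(np.sum(r * l**2) / n_runs),
        "gln": float(np.sum(r.sum(axis=1) ** 2) / n_runs),
        "rln": float(np.sum(r.sum(axis=0) ** 2) / n_runs),
        "rp": float(n_runs / n_p),
        "lgre": float(np.sum(r / i**2) / n_runs),
        "hgre": float(np.sum(r * i**2) / n_runs),
        "srlge": float(np.sum(r / (i**2 * l**2)) / n_runs),
        "srhge": float(np.sum(r * i**2 / l**2) / n_runs),
        "lrlge": float(np.sum(r * l**2 / i**2) / n_runs),
        "lrhge": float(np.sum(r * i**2 * l**2) / n_runs),
    }
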