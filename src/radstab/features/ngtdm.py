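"""The 5 neighbouring gray-tone difference (NGTDM) statistics.

Standard coarseness / contrast / busyness / complexity / strength
definitions over per-level occurrence probabilities ``p_i`` and summed
neighbourhood deviations ``s_i``.  Coarseness is capped at 1e6 when the
ROI is perfectly homogeneous; ratios with zero denominators are NaN.
"""

from __future__ import annotations

import numpy as np

from radstab.features.matrices import NGTDMTable

COARSENESS_CAP = 1.0e6


def ngtdm_features(t: NGTDMTable) -> dict[str, float]:
    p = t.probabilities()
    s = t.s
    n_total = t.n_total
    levels = np.arange(1, t.ng + 1, dtype=np.float64)
    occ = p > 0
    n_gp = int(occ.sum())

    pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
    li, lj = np.meshgrid(levels[occ], levels[occ], indexing="ij")
    si, sj = np.meshgrid(s[occ], s[occ], indexing="ij")

    ps = float(np.sum(p * s))
    coarseness = min(COARSENESS_CAP, 1.0 / ps) if ps > 0 else COARSENESS_CAP

    if n_gp > 1:
        contrast = float(
            np.sum(pi * pj * (li - lj) ** 2) / (n_gp * (n_gp - 1)) * (s.sum() / n_total)
        )
    else:
        contrast = 0.0

    busy_den = float(np.sum(np.abs(li * pi - lj * pj)))
    busyness = ps / busy_den if busy_den > 0 else float("nan")

    complexity = float(np.sum(np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)) / n_total)

    s_sum = float(s.sum())
    strength = float(np.sum((pi + pj) * (li - lj) ** 2)) / s_sum if s_sum > 0 else float("nan")

    return {
        "coarseness": float(coarseness),
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
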