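"""Co-occurrence statistics: the 22 GLCM features and the 5 second-order features.

Both consume a normalized symmetric co-occurrence matrix.  Logarithms are
base 2.  Where a formula divides by a zero variance or entropy (degenerate
single-cell matrix), the value is NaN.
"""

from __future__ import annotations

import numpy as np

from radstab.features.matrices import TextureMatrix


def _marginals(p: np.ndarray):
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    # p_{x+y}(k), k = 2..2Ng and p_{|x-y|}(k), k = 0..Ng-1
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    return i, ii, jj, px, py, p_sum, p_diff


def _entropy2(q: np.ndarray) -> float:
    q = q[q > 0]
    return float(-np.sum(q * np.log2(q)))


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    p = m.probabilities()
    ng = p.shape[0]
    i, ii, jj, px, py, p_sum, p_diff = _marginals(p)

    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    k_sum = np.arange(2, 2 * ng + 1)
    k_diff = np.arange(ng)
    sum_avg = float(np.sum(k_sum * p_sum))
    diff_avg = float(np.sum(k_diff * p_diff))

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    joint = px[:, None] * py[None, :]
    pos = p > 0
    hxy1 = float(-np.sum(p[pos] * np.log2(joint[pos])))
    jpos = joint > 0
    hxy2 = float(-np.sum(joint[jpos] * np.log2(joint[jpos])))

    autocorr = float(np.sum(ii * jj * p))
    corr = (
        (autocorr - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else float("nan")
    )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else float("nan")
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2))

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "cluster_shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "cluster_tendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": _entropy2(p_diff),
        "difference_variance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "energy": float(np.sum(p**2)),
        "entropy": hxy,
        "homogeneity": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "inverse_difference": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": inv_var,
        "joint_average": mu_x,
        "joint_variance": float(np.sum((ii - mu_x) ** 2 * p)),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": _entropy2(p_sum),
        "sum_variance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
    }


def secondorder_features(m: TextureMatrix) -> dict[str, float]:
    """Five co-occurrence summaries not in the 22-feature GLCM list."""
    p = m.probabilities()
    _, ii, jj, _, _, p_sum, p_diff = _marginals(p)
    return {
        "dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "pair_average_intensity": float(np.sum((ii + jj) / 2.0 * p)),
        "joint_maximum_complement": float(1.0 - p.max()),
        "difference_uniformity": float(np.sum(p_diff**2)),
        "sum_uniformity": float(np.sum(p_sum**2)),
    }
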