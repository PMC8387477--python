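"""First-order (histogram / intensity) features: 46 named statistics.

Raw-intensity statistics use the raw in-mask values; ``hist_*`` statistics
use the discretized levels.  Statistics whose formula divides by zero on a
degenerate ROI are returned as NaN — the shared "undefined" marker — never
as an arbitrary number.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from radstab.discretize import DiscretizedROI
from radstab.imaging import VolumeWithMask


def _safe_div(a: float, b: float) -> float:
    return a / b if b != 0 else float("nan")


def firstorder_features(volume: VolumeWithMask, disc: DiscretizedROI) -> dict[str, float]:
    volume.require_roi()
    x = volume.intensities[volume.mask != 0].astype(np.float64)
    voxvol = float(np.prod(volume.spacing))
    n = x.size

    p = {q: float(np.percentile(x, q)) for q in (1, 5, 10, 25, 50, 75, 90, 95, 99)}
    mean = float(x.mean())
    median = p[50]
    var = float(x.var())  # population (n-denominator) moments throughout
    std = float(np.sqrt(var))
    iqr = p[75] - p[25]
    core = x[(x >= p[10]) & (x <= p[90])]

    out: dict[str, float] = {
        "mean": mean,
        "median": median,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "midrange": float((x.max() + x.min()) / 2),
        "variance": var,
        "std": std,
        "coeff_variation": _safe_div(std, mean),
        "skewness": float(stats.skew(x)) if var > 0 else float("nan"),
        "kurtosis": float(stats.kurtosis(x, fisher=False)) if var > 0 else float("nan"),
        "energy": float(np.sum(x**2)),
        "total_energy": voxvol * float(np.sum(x**2)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "sum": float(x.sum()),
        "mean_abs_dev": float(np.mean(np.abs(x - mean))),
        "robust_mean_abs_dev": float(np.mean(np.abs(core - core.mean()))),
        "median_abs_dev": float(np.median(np.abs(x - median))),
        "iqr": iqr,
        "quartile_dispersion": _safe_div(p[75] - p[25], p[75] + p[25]),
        "bowley_skewness": _safe_div(p[25] + p[75] - 2 * median, iqr),
        "trimmed_mean": float(stats.trim_mean(x, 0.1)) if n >= 3 else mean,
    }
    for q in (1, 5, 10, 25, 75, 90, 95, 99):
        out[f"p{q}"] = p[q]

    out.update(_histogram_stats(disc))
    return out


def _histogram_stats(disc: DiscretizedROI) -> dict[str, float]:
    levels = disc.roi_levels.astype(np.float64)
    ng = disc.ng
    counts = np.bincount(disc.roi_levels, minlength=ng + 1)[1:]
    probs = counts / counts.sum()
    occupied = probs > 0

    mu = float(np.sum(np.arange(1, ng + 1) * probs))
    var = float(np.sum((np.arange(1, ng + 1) - mu) ** 2 * probs))
    std = float(np.sqrt(var))
    centered = np.arange(1, ng + 1) - mu
    skew = _safe_div(float(np.sum(centered**3 * probs)), std**3)
    kurt = _safe_div(float(np.sum(centered**4 * probs)), var**2)

    return {
        "hist_mean": mu,
        "hist_variance": var,
        "hist_std": std,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_entropy": float(-np.sum(probs[occupied] * np.log2(probs[occupied]))),
        "uniformity": float(np.sum(probs**2)),
        "max_probability": float(probs.max()),
        "hist_mode": float(np.argmax(probs) + 1),
        "hist_median": float(np.median(levels)),
        "hist_p10": float(np.percentile(levels, 10)),
        "hist_p90": float(np.percentile(levels, 90)),
        "hist_iqr": float(np.percentile(levels, 75) - np.percentile(levels, 25)),
        "occupied_levels": float(np.count_nonzero(occupied)),
        "occupied_fraction": float(np.count_nonzero(occupied)) / ng,
        "hist_cv": _safe_div(std, mu),
    }
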