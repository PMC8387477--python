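"""The ordered 595-entry feature registry.

46 first-order features, 61 spatial-domain texture features
(5 second-order + 22 GLCM + 11 GLRLM + 5 LBP + 13 GLSZM + 5 NGTDM) and
488 wavelet-domain features (the same 61 texture features on each of 8
undecimated subbands).  Names are ``<family>_<statistic>`` optionally
prefixed by ``wavelet-<subband>_``; order is fixed so feature vectors align.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FIRSTORDER_NAMES = [
    # raw-intensity statistics (30)
    "mean", "median", "minimum", "maximum", "range", "midrange",
    "variance", "std", "coeff_variation", "skewness", "kurtosis",
    "energy", "total_energy", "rms", "sum",
    "mean_abs_dev", "robust_mean_abs_dev", "median_abs_dev",
    "iqr", "quartile_dispersion", "bowley_skewness", "trimmed_mean",
    "p1", "p5", "p10", "p25", "p75", "p90", "p95", "p99",
    # discrete-level histogram statistics (16)
    "hist_mean", "hist_variance", "hist_std", "hist_skewness", "hist_kurtosis",
    "hist_entropy", "uniformity", "max_probability", "hist_mode", "hist_median",
    "hist_p10", "hist_p90", "hist_iqr", "occupied_levels", "occupied_fraction",
    "hist_cv",
]

SECONDORDER_NAMES = [
    "dissimilarity", "pair_average_intensity", "joint_maximum_complement",
    "difference_uniformity", "sum_uniformity",
]

GLCM_NAMES = [
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "energy", "entropy", "homogeneity",
    "inverse_difference", "imc1", "imc2", "inverse_variance",
    "joint_average", "joint_variance", "maximum_probability",
    "sum_average", "sum_entropy", "sum_variance",
]

GLRLM_NAMES = [
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
]

LBP_NAMES = ["energy", "entropy", "mean", "variance", "uniform_fraction"]

GLSZM_NAMES = [
    "sae", "lae", "gln", "zsn", "zp",
    "lgze", "hgze", "salge", "sahge", "lalge", "lahge",
    "glv", "zsv",
]

NGTDM_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

#: texture families in catalog order, with their per-family statistic lists
TEXTURE_FAMILIES = [
    ("secondorder", SECONDORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("lbp", LBP_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
]

#: the eight undecimated subbands: level-1 then level-2, raster order
SUBBAND_NAMES = ["LL", "LH", "HL", "HH", "LL2", "LH2", "HL2", "HH2"]


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    family: str
    transform: str  # "none" or "wavelet-<subband>"


class FeatureCatalog:
    """Ordered, immutable registry of the full feature set."""

    def __init__(self, entries: list[CatalogEntry]):
        self.entries = tuple(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def counts(self, transform: str | None = None) -> dict[str, int]:
        """Per-family entry counts, optionally restricted to one transform."""
        out: dict[str, int] = {}
        for e in self.entries:
            if transform is not None and e.transform != transform:
                continue
            out[e.family] = out.get(e.family, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.family, e.transform) for e in self.entries],
            columns=["name", "family", "transform"],
        )

    def version_hash(self) -> str:
        import hashlib

        blob = "\n".join(f"{e.name}|{e.family}|{e.transform}" for e in self.entries)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_catalog() -> FeatureCatalog:
    entries = [CatalogEntry(f"firstorder_{n}", "firstorder", "none") for n in FIRSTORDER_NAMES]
    for family, stats in TEXTURE_FAMILIES:
        entries += [CatalogEntry(f"{family}_{n}", family, "none") for n in stats]
    for sb in SUBBAND_NAMES:
        for family, stats in TEXTURE_FAMILIES:
            entries += [
                CatalogEntry(f"wavelet-{sb}_{family}_{n}", family, f"wavelet-{sb}") for n in stats
            ]
    return FeatureCatalog(entries)


def _check_counts() -> None:
    cat = default_catalog()
    spatial = cat.counts("none")
    expected = {
        "firstorder": 46, "secondorder": 5, "glcm": 22,
        "glrlm": 11, "lbp": 5, "glszm": 13, "ngtdm": 5,
    }
    if spatial != expected:
        raise AssertionError(f"spatial family counts {spatial} != {expected}")
    if len(cat) != 595:
        raise AssertionError(f"catalog has {len(cat)} entries, expected 595")


_check_counts()
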