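"""Full-catalog feature extraction for one image + ROI.

``extract_all`` runs discretization, the first-order family, the six
spatial-domain texture families, and the 8-subband wavelet block, returning
a name -> value mapping aligned with :func:`radstab.catalog.default_catalog`.
Undefined values are NaN — never silently zero; a failure inside one family
marks only that family undefined and is logged.
"""

from __future__ import annotations

import logging

import numpy as np

from radstab.catalog import SUBBAND_NAMES, TEXTURE_FAMILIES, default_catalog
from radstab.discretize import DEFAULT_NG, DiscretizedROI, discretize_fixed_bins
from radstab.features.cooccurrence import glcm_features, secondorder_features
from radstab.features.firstorder import firstorder_features
from radstab.features.lbp import lbp_features
from radstab.features.matrices import glcm_matrix, glrlm_matrix, glszm_matrix, ngtdm_table
from radstab.features.ngtdm import ngtdm_features
from radstab.features.runlength import glrlm_features
from radstab.features.sizezone import glszm_features
from radstab.imaging import VolumeWithMask
from radstab.wavelet import wavelet_decompose

logger = logging.getLogger(__name__)

_CATALOG = default_catalog()

_FAMILY_SIZES = dict((fam, len(stats)) for fam, stats in TEXTURE_FAMILIES)


def _nan_family(family: str) -> dict[str, float]:
    stats = dict(TEXTURE_FAMILIES)[family]
    return {f"{family}_{s}": float("nan") for s in stats}


def extract_texture_block(
    intensities: np.ndarray, disc: DiscretizedROI, label: str = ""
) -> dict[str, float]:
    """The 61 texture features (secondorder/glcm/glrlm/lbp/glszm/ngtdm) of one
    discretized ROI; ``intensities`` feeds LBP, which works pre-discretization."""
    out: dict[str, float] = {}

    def run(family: str, fn) -> None:
        try:
            vals = fn()
        except Exception as exc:
            logger.debug("family %s%s undefined: %s", label, family, exc)
            out.update(_nan_family(family))
            return
        out.update({f"{family}_{k}": v for k, v in vals.items()})

    glcm = None
    try:
        glcm = glcm_matrix(disc)
        if glcm.total == 0:
            glcm = None
    except Exception:
        glcm = None
    if glcm is None:
        out.update(_nan_family("secondorder"))
        out.update(_nan_family("glcm"))
    else:
        run("secondorder", lambda: secondorder_features(glcm))
        run("glcm", lambda: glcm_features(glcm))
    run("glrlm", lambda: glrlm_features(glrlm_matrix(disc)))
    run("lbp", lambda: lbp_features(intensities, disc.mask))
    run("glszm", lambda: glszm_features(glszm_matrix(disc)))
    run("ngtdm", lambda: ngtdm_features(ngtdm_table(disc)))
    return out


def extract_all(
    volume: VolumeWithMask, ng: int = DEFAULT_NG, wavelet_family: str = "haar"
) -> dict[str, float]:
    """Compute the full 595-feature vector for one image + ROI."""
    volume.require_roi()
    disc = discretize_fixed_bins(volume, ng)

    values: dict[str, float] = {}
    try:
        fo = firstorder_features(volume, disc)
    except Exception as exc:
        logger.warning("first-order family undefined: %s", exc)
        from radstab.catalog import FIRSTORDER_NAMES

        fo = {n: float("nan") for n in FIRSTORDER_NAMES}
    values.update({f"firstorder_{k}": v for k, v in fo.items()})

    values.update(extract_texture_block(volume.intensities, disc))

    subbands = wavelet_decompose(volume.intensities, wavelet_family)
    for sb in SUBBAND_NAMES:
        data = subbands[sb]
        sub_vol = VolumeWithMask(data, volume.spacing, volume.mask)
        sub_disc = discretize_fixed_bins(sub_vol, ng)
        block = extract_texture_block(data, sub_disc, label=f"wavelet-{sb}_")
        values.update({f"wavelet-{sb}_{k}": v for k, v in block.items()})

    ordered = {name: values[name] for name in _CATALOG.names}
    if len(ordered) != len(_CATALOG):
        missing = set(_CATALOG.names) - set(values)
        raise AssertionError(f"extractor returned {len(ordered)} values; missing {sorted(missing)[:5]}")
    return ordered
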