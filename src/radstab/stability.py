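"""Per-feature agreement analysis between paired acquisitions.

Lin's concordance correlation coefficient per feature, stability
classification at a strict threshold, per-stratum/per-family summaries with
bootstrap confidence intervals for the median, and McNemar comparison of
stable-feature indicators between two fast sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from radstab.catalog import FeatureCatalog, default_catalog
from radstab.imaging import REFERENCE_SEQUENCE

logger = logging.getLogger(__name__)

STABILITY_THRESHOLD = 0.85
#: switch from the exact binomial to the continuity-corrected chi-square
MCNEMAR_EXACT_MAX = 25
LESION_STRATA = ("acute", "chronic", "overall")


def lin_ccc(x, y) -> tuple[float, int]:
    """Lin's concordance correlation coefficient and the effective n.

    ``rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with
    n-denominator sample moments.  Pairs containing NaN are dropped first.
    Returns NaN when fewer than 3 pairs remain.  When the denominator is
    zero the two lists are identical constants — perfect agreement — and the
    coefficient is reported as 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return float("nan"), n
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0, n  # identical constant lists: perfect concordance
    return float(2.0 * sxy / denom), n


@dataclass
class CCCResult:
    feature_name: str
    ccc: float  # NaN when undefined
    n: int
    stable: bool = False
    reason: str | None = None


def classify_stability(
    results: list[CCCResult], threshold: float = STABILITY_THRESHOLD
) -> list[CCCResult]:
    """Stable iff the CCC is defined and strictly exceeds the threshold."""
    for r in results:
        if not np.isfinite(r.ccc):
            r.stable = False
            r.reason = r.reason or "ccc undefined"
        else:
            r.stable = bool(r.ccc > threshold)
    return results


def ccc_table(paired: pd.DataFrame, threshold: float = STABILITY_THRESHOLD) -> pd.DataFrame:
    """Per-feature CCC/stability from a long frame with columns
    ``feature_name, subject_id, x, y``."""
    rows = []
    for name, grp in paired.groupby("feature_name", sort=True):
        ccc, n = lin_ccc(grp["x"].to_numpy(), grp["y"].to_numpy())
        rows.append(
            {
                "feature_name": name,
                "ccc": ccc,
                "n": n,
                "stable": bool(np.isfinite(ccc) and ccc > threshold),
            }
        )
    return pd.DataFrame(rows)


def median_ccc_ci(
    values, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """Median of the defined CCCs with a seeded percentile-bootstrap 95% CI."""
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"need at least 2 defined CCC values, got {vals.size}")
    med = float(np.median(vals))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boot = np.median(vals[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return med, float(lo), float(hi)


@dataclass
class McNemarResult:
    b: int  # stable under A only
    c: int  # stable under B only
    n_concordant: int
    statistic: float
    p_value: float
    method: str  # "exact-binomial" | "chi2-cc" | "degenerate"


def mcnemar_test(stable_a, stable_b) -> McNemarResult:
    """Paired comparison of two stability indicator lists.

    Discordant counts drive the test: the continuity-corrected chi-square
    ``(|b-c|-1)^2/(b+c)`` with 1 df when ``b+c >= 25``, otherwise the exact
    two-sided binomial ``2 P(X >= max(b,c))``, ``X ~ Bin(b+c, 1/2)``.
    """
    a = np.asarray(stable_a, dtype=bool)
    bb = np.asarray(stable_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {bb.shape}")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n_conc = int(a.size - b - c)
    if b + c == 0:
        return McNemarResult(b, c, n_conc, 0.0, 1.0, "degenerate")
    if b + c >= MCNEMAR_EXACT_MAX:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(stat, df=1))
        return McNemarResult(b, c, n_conc, float(stat), p, "chi2-cc")
    k = max(b, c)
    p = min(1.0, 2.0 * float(stats.binom.sf(k - 1, b + c, 0.5)))
    return McNemarResult(b, c, n_conc, float(min(b, c)), p, "exact-binomial")


# ---------------------------------------------------------------------------
# Study-level orchestration
# ---------------------------------------------------------------------------

def build_paired_table(
    features: pd.DataFrame,
    group: str,
    lesion_class: str,
    mask_kind: str,
    fast_sequence: str,
    reference: str = REFERENCE_SEQUENCE,
) -> pd.DataFrame:
    """Align reference vs fast feature values subject-by-subject.

    ``features`` is the long-form extraction table.  ``lesion_class`` may be
    "acute", "chronic" or "overall" (pooled).  Whole masks pair each
    sequence's own mask; intersection masks pair the shared
    conventional∩fast mask applied on both images (matched via ``pairing``).
    """
    df = features[features["group"] == group]
    if lesion_class != "overall":
        df = df[df["lesion_class"] == lesion_class]
    df = df[df["mask_kind"] == mask_kind]
    if mask_kind == "intersection":
        df = df[df["pairing"] == fast_sequence]
    ref = df[df["sequence"] == reference]
    fast = df[df["sequence"] == fast_sequence]
    merged = ref.merge(
        fast, on=["feature_name", "subject_id"], suffixes=("_ref", "_fast")
    )
    return merged.rename(columns={"value_ref": "x", "value_fast": "y"})[
        ["feature_name", "subject_id", "x", "y"]
    ]


@dataclass
class StudyReport:
    summary: pd.DataFrame  # one row per stratum
    mcnemar: pd.DataFrame  # one row per (group, lesion class, mask kind)
    ccc_matrix: pd.DataFrame  # features x strata (NaN for undefined)


def run_stability_study(
    features: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    threshold: float = STABILITY_THRESHOLD,
    n_boot: int = 2000,
    seed: int = 0,
) -> StudyReport:
    """Full per-stratum stability report plus fast-vs-fast McNemar tests.

    Strata are all (group, lesion class incl. pooled "overall", mask kind,
    fast sequence) combinations present in the table.  The stable-feature
    proportion uses the full catalog size as denominator; undefined CCCs
    count as not stable but stay NaN in the exported matrix.
    """
    catalog = catalog or default_catalog()
    n_catalog = len(catalog)
    summary_rows = []
    mcnemar_rows = []
    ccc_cols: dict[str, pd.Series] = {}
    stable_by_stratum: dict[tuple, pd.Series] = {}

    for group in sorted(features["group"].unique()):
        gdf = features[features["group"] == group]
        fast_seqs = sorted(s for s in gdf["sequence"].unique() if s != REFERENCE_SEQUENCE)
        for mask_kind in sorted(gdf["mask_kind"].unique()):
            for lesion_class in LESION_STRATA:
                for fast in fast_seqs:
                    paired = build_paired_table(features, group, lesion_class, mask_kind, fast)
                    if paired.empty:
                        logger.warning(
                            "missing stratum: group=%s lesion=%s mask=%s fast=%s",
                            group, lesion_class, mask_kind, fast,
                        )
                        continue
                    table = ccc_table(paired, threshold)
                    table = table.set_index("feature_name").reindex(catalog.names)
                    defined = table["ccc"].dropna()
                    if len(defined) >= 2:
                        med, lo, hi = median_ccc_ci(defined.to_numpy(), n_boot, seed)
                    else:
                        med = lo = hi = float("nan")
                    n_stable = int(table["stable"].fillna(False).sum())
                    key = (group, lesion_class, mask_kind, fast)
                    stable_by_stratum[key] = table["stable"].fillna(False).astype(bool)
                    col = f"{group}|{lesion_class}|{mask_kind}|{fast}"
                    ccc_cols[col] = table["ccc"]
                    fam = catalog.to_frame().set_index("name")["family"]
                    fam_counts = (
                        table["stable"].fillna(False).groupby(fam).sum().astype(int).to_dict()
                    )
                    summary_rows.append(
                        {
                            "group": group,
                            "lesion_class": lesion_class,
                            "mask_kind": mask_kind,
                            "fast_sequence": fast,
                            "n_features": n_catalog,
                            "n_stable": n_stable,
                            "proportion_stable": n_stable / n_catalog,
                            "median_ccc": med,
                            "ci_lo": lo,
                            "ci_hi": hi,
                            **{f"stable_{k}": v for k, v in sorted(fam_counts.items())},
                        }
                    )
                if len(fast_seqs) == 2:
                    a, b = fast_seqs
                    ka = (group, lesion_class, mask_kind, a)
                    kb = (group, lesion_class, mask_kind, b)
                    if ka in stable_by_stratum and kb in stable_by_stratum:
                        res = mcnemar_test(
                            stable_by_stratum[ka].to_numpy(), stable_by_stratum[kb].to_numpy()
                        )
                        mcnemar_rows.append(
                            {
                                "group": group,
                                "lesion_class": lesion_class,
                                "mask_kind": mask_kind,
                                "sequence_a": a,
                                "sequence_b": b,
                                "b_only_a": res.b,
                                "c_only_b": res.c,
                                "statistic": res.statistic,
                                "p_value": res.p_value,
                                "method": res.method,
                            }
                        )

    summary = pd.DataFrame(summary_rows)
    mcnemar = pd.DataFrame(mcnemar_rows)
    ccc_matrix = pd.DataFrame(ccc_cols, index=pd.Index(catalog.names, name="feature_name"))
    return StudyReport(summary, mcnemar, ccc_matrix)
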