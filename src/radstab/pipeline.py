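"""Cohort-level orchestration: manifest loading and batch feature extraction."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from radstab.catalog import default_catalog
from radstab.features.extract import extract_all
from radstab.imaging import (
    REFERENCE_SEQUENCE,
    ExtractionTask,
    MaskKind,
    SubjectRecord,
    VolumeWithMask,
    enumerate_mask_set,
    intersect_masks,
    read_mask,
    read_volume,
    resample_mask,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["subject_id", "group", "lesion_class", "sequence", "volume_path", "mask_path"]


def load_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV into subject records; paths are resolved
    relative to the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    base = path.parent
    records: dict[str, SubjectRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        rec = records.setdefault(
            sid, SubjectRecord(sid, str(row["group"]), str(row["lesion_class"]))
        )
        rec.sequences[str(row["sequence"])] = (
            str(base / row["volume_path"]),
            str(base / row["mask_path"]),
        )
    return list(records.values())


def _load_subject(rec: SubjectRecord) -> dict[str, VolumeWithMask]:
    vols: dict[str, VolumeWithMask] = {}
    for seq, (vol_path, mask_path) in rec.sequences.items():
        vol = read_volume(
            vol_path,
            meta={
                "subject_id": rec.subject_id,
                "group": rec.group,
                "lesion_class": rec.lesion_class,
                "sequence": seq,
            },
        )
        vols[seq] = vol.with_mask(read_mask(mask_path, vol))
    return vols


def _task_volume(task: ExtractionTask, vols: dict[str, VolumeWithMask]) -> VolumeWithMask:
    """The image + mask a task extracts from (builds intersection masks)."""
    vol = vols[task.sequence]
    if task.mask_kind is MaskKind.WHOLE:
        return vol
    other_seq = task.pairing if task.sequence == REFERENCE_SEQUENCE else REFERENCE_SEQUENCE
    other = vols[other_seq]
    other_mask = resample_mask(other.mask, other.spacing, vol.shape, vol.spacing)
    return vol.with_mask(intersect_masks(vol.mask, other_mask))


def run_extraction(
    cohort: list[SubjectRecord], ng: int = 32, wavelet_family: str = "haar"
) -> pd.DataFrame:
    """Extract the full feature catalog for every mask role of every subject.

    Returns the long-form table consumed by the stability analysis; failed
    tasks are logged and skipped, the rest complete.
    """
    catalog = default_catalog()
    cat_frame = catalog.to_frame().set_index("name")
    tasks = enumerate_mask_set(cohort)
    by_subject: dict[str, list[ExtractionTask]] = {}
    for t in tasks:
        by_subject.setdefault(t.subject_id, []).append(t)

    frames = []
    n_failed = 0
    for rec in cohort:
        if rec.subject_id not in by_subject:
            continue
        try:
            vols = _load_subject(rec)
        except Exception as exc:
            n_failed += len(by_subject[rec.subject_id])
            logger.warning("subject %s failed to load: %s", rec.subject_id, exc)
            continue
        for task in by_subject[rec.subject_id]:
            t0 = time.perf_counter()
            try:
                target = _task_volume(task, vols)
                values = extract_all(target, ng=ng, wavelet_family=wavelet_family)
            except Exception as exc:
                n_failed += 1
                logger.warning("task %s failed: %s", task, exc)
                continue
            frame = pd.DataFrame(
                {"feature_name": list(values), "value": list(values.values())}
            )
            frame["family"] = cat_frame.loc[frame["feature_name"], "family"].to_numpy()
            frame["transform"] = cat_frame.loc[frame["feature_name"], "transform"].to_numpy()
            frame["subject_id"] = task.subject_id
            frame["group"] = task.group
            frame["lesion_class"] = task.lesion_class
            frame["sequence"] = task.sequence
            frame["mask_kind"] = task.mask_kind.value
            frame["pairing"] = task.pairing
            frames.append(frame)
            logger.info(
                "extracted %s/%s/%s/%s in %.2fs",
                task.subject_id, task.sequence, task.mask_kind.value, task.pairing,
                time.perf_counter() - t0,
            )
    if n_failed:
        logger.warning("extraction finished with %d failed task(s)", n_failed)
    if not frames:
        return pd.DataFrame(
            columns=[
                "subject_id", "group", "lesion_class", "sequence", "mask_kind",
                "pairing", "feature_name", "family", "transform", "value",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    return out[
        [
            "subject_id", "group", "lesion_class", "sequence", "mask_kind",
            "pairing", "feature_name", "family", "transform", "value",
        ]
    ]
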