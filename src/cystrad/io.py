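"""File IO: NIfTI volumes, feature-table CSVs, record CSVs, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import FukuokaRecord
from .tables import (
    GRADE_COLUMN,
    HIGH_GRADE,
    ID_COLUMN,
    LOW_GRADE,
    parse_grade,
    validate_feature_table,
)
from .texture import ImageVolume, ROIMask


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(
        voxels=np.asarray(img.dataobj, dtype=float),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def save_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def load_mask(path: str | Path, region_kind: str = "cyst") -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.dataobj) > 0, region_kind=region_kind)


def save_cohort(
    cohort: list[tuple[ImageVolume, ROIMask, str]],
    outdir: str | Path,
    compress: bool = False,
) -> pd.DataFrame:
    """Write image/mask NIfTI pairs plus a labels CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for k, (image, mask, grade) in enumerate(cohort):
        sid = f"S{k + 1:03d}"
        save_volume(image, outdir / f"{sid}_image{ext}")
        save_mask(mask, outdir / f"{sid}_mask{ext}")
        rows.append({ID_COLUMN: sid, GRADE_COLUMN: grade})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "labels.csv", index=False)
    return manifest


def load_cohort(indir: str | Path) -> tuple[list[tuple[ImageVolume, ROIMask, str]], list[str]]:
    """Read a directory produced by :func:`save_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "labels.csv")
    cohort, ids = [], []
    for _, row in manifest.iterrows():
        sid = str(row[ID_COLUMN])
        paths = sorted(indir.glob(f"{sid}_image.nii*"))
        mpaths = sorted(indir.glob(f"{sid}_mask.nii*"))
        if not paths or not mpaths:
            raise FileNotFoundError(f"missing image/mask pair for {sid} in {indir}")
        cohort.append((load_volume(paths[0]), load_mask(mpaths[0]), str(row[GRADE_COLUMN])))
        ids.append(sid)
    return cohort, ids


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table with grades spelled as HG/LG."""
    out = table.copy()
    out[GRADE_COLUMN] = [HIGH_GRADE if g == 1 else LOW_GRADE for g in out[GRADE_COLUMN]]
    out.to_csv(path, index=False)


def load_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Grade labels may be HG/LG or 1/0.  Errors name the offending row or
    column; row numbers are 0-based data rows.
    """
    raw = pd.read_csv(path)
    if ID_COLUMN not in raw.columns:
        raise ValueError(f"{path}: missing required column {ID_COLUMN!r}")
    if GRADE_COLUMN not in raw.columns:
        raise ValueError(f"{path}: missing required column {GRADE_COLUMN!r}")
    try:
        raw[GRADE_COLUMN] = [parse_grade(g) for g in raw[GRADE_COLUMN]]
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    for col in raw.columns:
        if col in (ID_COLUMN, GRADE_COLUMN):
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(raw.index[bad][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        raw[col] = coerced
    return validate_feature_table(raw)


def write_fukuoka_csv(records: list[FukuokaRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def load_fukuoka_csv(path: str | Path) -> list[FukuokaRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        records.append(
            FukuokaRecord(
                subject_id=str(row["subject_id"]),
                main_duct_involvement=bool(row["main_duct_involvement"]),
                cyst_size_cm=float(row["cyst_size_cm"]),
                mural_nodule=bool(row["mural_nodule"]),
                mpd_diameter_mm=float(row["mpd_diameter_mm"]),
                positive_cytology=bool(row["positive_cytology"]),
                symptomatic=bool(row["symptomatic"]),
                grade=str(row["grade"]),
            )
        )
    return records


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
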