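"""Serialisation of volumes, VOI sets, SBR tables, models and verdicts.

Formats: NIfTI-1 (RAS, isotropic voxels recorded in the header) for volumes
and label maps, CSV (UTF-8, header row) for tabular records, JSON for code
tables and fitted models.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError
from .normdb import ScanVerdict
from .quantify import SBRRecord, VOICode, VOISet
from .synthdata import CountVolume

SBR_COLUMNS = [
    "subject_id", "age", "scanner_id", "mode", "quantifier",
    "side", "structure", "measured_sbr", "calibrated_sbr",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(volume: CountVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64),
                          _affine(volume.voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CountVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not all(math.isclose(z, zooms[0], rel_tol=1e-6) for z in zooms):
        raise ConfigError(f"{path}: anisotropic voxels are not supported")
    return CountVolume(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=float(zooms[0]),
    )


def save_voi_set(vois: VOISet, labels_path: str | Path, codes_path: str | Path) -> None:
    img = nib.Nifti1Image(vois.labels.astype(np.int16), _affine(vois.voxel_size_mm))
    nib.save(img, str(labels_path))
    payload = {
        str(code): {"side": entry.side, "structure": entry.structure, "role": entry.role}
        for code, entry in vois.codes.items()
    }
    Path(codes_path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_voi_set(labels_path: str | Path, codes_path: str | Path) -> VOISet:
    img = nib.load(str(labels_path))
    zooms = img.header.get_zooms()[:3]
    try:
        payload = json.loads(Path(codes_path).read_text(encoding="utf-8"))
        codes = {
            int(code): VOICode(entry["side"], entry["structure"], entry["role"])
            for code, entry in payload.items()
        }
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ConfigError(f"{codes_path}: malformed VOI code table: {exc}") from exc
    return VOISet(
        labels=np.asarray(img.dataobj).astype(np.int16),
        codes=codes,
        voxel_size_mm=float(zooms[0]),
    )


def sbr_records_to_frame(records: Iterable[SBRRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "age": r.age,
            "scanner_id": r.scanner_id,
            "mode": r.mode,
            "quantifier": r.quantifier,
            "side": r.side,
            "structure": r.structure,
            "measured_sbr": r.measured_sbr,
            "calibrated_sbr": r.calibrated_sbr,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SBR_COLUMNS)


def save_sbr_records(records: Iterable[SBRRecord], path: str | Path) -> None:
    sbr_records_to_frame(records).to_csv(path, index=False)


def load_sbr_records(path: str | Path) -> list[SBRRecord]:
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ConfigError(f"{path}: malformed SBR CSV: {exc}") from exc
    missing = set(SBR_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: SBR CSV missing columns {sorted(missing)}")
    records = []
    for idx, row in frame.iterrows():
        try:
            calibrated = row["calibrated_sbr"]
            records.append(
                SBRRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    scanner_id=str(row["scanner_id"]),
                    mode=str(row["mode"]),
                    quantifier=str(row["quantifier"]),
                    side=str(row["side"]),
                    structure=str(row["structure"]),
                    measured_sbr=float(row["measured_sbr"]),
                    calibrated_sbr=None if pd.isna(calibrated) else float(calibrated),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: bad SBR record at row {idx + 2}: {exc}") from exc
    return records


def save_verdicts(verdicts: Sequence[ScanVerdict], path: str | Path) -> None:
    rows = []
    for v in verdicts:
        row = {"subject_id": v.subject_id, "rule": v.rule,
               "scan_abnormal": v.scan_abnormal}
        for (side, structure), flag in sorted(v.region_flags.items()):
            row[f"abnormal_{side}_{structure}"] = flag
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
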