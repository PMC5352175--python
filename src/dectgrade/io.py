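"""On-disk formats: NIfTI volumes, CSV feature tables, JSON configs.

Volumes are written with a diagonal affine carrying the voxel spacing, so a
write-read round trip preserves both the array and the spacing exactly.
Feature CSVs are UTF-8, comma-separated with '.' decimals; missing values
are empty cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError


def write_volume(path, array: np.ndarray, spacing) -> None:
    array = np.asarray(array, dtype=np.float64)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(array, affine), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing


def write_mask(path, mask: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, ...]]:
    data, spacing = read_volume(path)
    return data > 0.5, spacing


def write_feature_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_feature_csv(path, require_columns=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in require_columns if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} lacks required column(s) {missing}")
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"JSON file not found: {path}")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {path}: {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
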