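"""File interchange: NIfTI volumes/masks, landmark CSVs, voxel tables, JSON.

Axis order is (x, y, z) everywhere; NIfTI affines are diagonal
(spacing on the diagonal, origin in the last column), matching the
axis-aligned grids this package works on.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import GridGeometry, ROIMask, SUVVolume
from .registration import LandmarkSet
from .stats import VOXEL_TABLE_COLUMNS, GroupComparison, LogisticFit, ROCResult

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_landmarks",
    "load_landmarks",
    "save_voxel_table",
    "load_voxel_table",
    "fit_to_dict",
    "roc_to_dict",
    "comparison_to_dict",
    "save_json",
]


def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(geometry.voxel_size_mm)
    aff[:3, 3] = geometry.origin_mm
    return aff


def _geometry_from(img: nib.Nifti1Image) -> GridGeometry:
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off, 0, atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI grids are supported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return GridGeometry(tuple(int(n) for n in img.shape[:3]), spacing, origin)


def save_volume(volume: SUVVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.geometry))
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> SUVVolume:
    img = nib.load(str(path))
    return SUVVolume(np.asarray(img.dataobj, dtype=np.float64), _geometry_from(img))


def save_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.geometry))
    nib.save(img, path)
    return path


def load_mask(path: str | Path, label: str = "primary") -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.dataobj) > 0, _geometry_from(img), label)


def save_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    names = landmarks.names or [f"p{i}" for i in range(len(landmarks))]
    df = pd.DataFrame(landmarks.points_mm, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "name", names)
    df.to_csv(path, index=False)
    return path


def load_landmarks(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float), list(df["name"]))


def save_voxel_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[VOXEL_TABLE_COLUMNS].to_csv(path, index=False)
    return path


def load_voxel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VOXEL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"voxel table {path} missing columns {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def fit_to_dict(fit: LogisticFit) -> dict:
    d = asdict(fit)
    d["covariance"] = np.asarray(fit.covariance).tolist()
    return d


def roc_to_dict(roc: ROCResult) -> dict:
    return {
        "auc": roc.auc,
        "n_positive": roc.n_positive,
        "n_negative": roc.n_negative,
        "thresholds": np.asarray(roc.thresholds).tolist(),
        "tpr": np.asarray(roc.tpr).tolist(),
        "fpr": np.asarray(roc.fpr).tolist(),
    }


def comparison_to_dict(cmp: GroupComparison) -> dict:
    return asdict(cmp)


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path
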