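"""NIfTI / JSON / CSV readers and writers.

Volumes go to NIfTI-1 with a diagonal affine built from the voxel size;
atlases are integer NIfTI plus a JSON sidecar mapping labels to region
names.  Round trips are lossless for float32 data and integer labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import LabelAtlas, Volume3D


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected layout."""


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=np.float32), _affine(volume.voxel_size_mm)
    )
    nib.save(img, path)
    return path


def read_volume(path: str | Path, identifier: str = "") -> Volume3D:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected 3 spatial dimensions (header dim), got {data.ndim}"
        )
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data), voxel, identifier or path.stem)


def write_atlas(atlas: LabelAtlas, path: str | Path) -> tuple[Path, Path]:
    """Write labels as integer NIfTI plus a ``<stem>.labels.json`` sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(atlas.labels, dtype=np.int16), _affine(atlas.voxel_size_mm)
    )
    nib.save(img, path)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    sidecar = path.with_name(stem + ".labels.json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in atlas.region_names.items()}, indent=1)
    )
    return path, sidecar


def read_atlas(path: str | Path) -> LabelAtlas:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise FormatError(f"{path}: expected 3 spatial dimensions, got {labels.ndim}")
    if not np.allclose(labels, np.round(labels)):
        raise FormatError(f"{path}: atlas datatype holds non-integer values")
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    sidecar = path.with_name(stem + ".labels.json")
    if not sidecar.exists():
        raise FormatError(f"missing label sidecar {sidecar}")
    names = {int(k): str(v) for k, v in json.loads(sidecar.read_text()).items()}
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelAtlas(labels.astype(np.int32), names, voxel)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
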