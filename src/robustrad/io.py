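"""NIfTI and table I/O.

Volumes are written as NIfTI-1 with the affine ``diag(spacing)``; dynamic
series carry their frame axis (times or b-values) in a JSON sidecar named
``<stem>.meta.json`` next to the image. Round-trips preserve the voxel
data bit-for-bit (dtype included).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from robustrad.core import DynamicSeries, Mask3D, ParametricMap
from robustrad.features.extract import N_FEATURES_PER_MAP


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _spacing_from(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + ".meta.json")


def save_series(series: DynamicSeries, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data, _affine(series.spacing))
    img.header.set_zooms(series.spacing + (1.0,))
    nib.save(img, path)
    meta = {"kind": series.kind, "axis": series.axis.tolist()}
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def load_series(path) -> DynamicSeries:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    # also accept a bare .bval-style list for the axis
    return DynamicSeries(
        data=np.asanyarray(img.dataobj),
        axis=np.asarray(meta["axis"], dtype=float),
        spacing=_spacing_from(img),
        kind=meta["kind"],
    )


def save_mask(mask: Mask3D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, path)
    return path


def load_mask(path) -> Mask3D:
    img = nib.load(Path(path))
    data = np.asanyarray(img.dataobj)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path}: mask contains non-binary values {uniq[:10]}")
    return Mask3D(data.astype(bool), _spacing_from(img))


def save_map(pmap: ParametricMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(pmap.data.astype(np.float32), _affine(pmap.spacing))
    nib.save(img, path)
    return path


def load_map(path, name: str) -> ParametricMap:
    img = nib.load(Path(path))
    return ParametricMap(name, np.asanyarray(img.dataobj).astype(float), _spacing_from(img))


def check_same_grid(a_shape, b_shape) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"grid mismatch: {tuple(a_shape)} vs {tuple(b_shape)}")


def save_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_feature_table(path, n_maps: int = 12) -> pd.DataFrame:
    """Load and schema-check a feature table CSV (id columns + features)."""
    table = pd.read_csv(Path(path))
    for col in ("lesion_id", "roi_variant"):
        if col not in table.columns:
            raise ValueError(f"feature table missing {col!r} column")
    n_feat = len(table.columns) - 2
    expected = n_maps * N_FEATURES_PER_MAP
    if n_feat != expected:
        raise ValueError(
            f"feature table has {n_feat} feature columns, expected {expected} "
            f"({n_maps} maps x {N_FEATURES_PER_MAP})"
        )
    return table
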