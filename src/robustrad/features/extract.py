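"""Assembly of per-lesion feature vectors and the cohort feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from robustrad.core import ALL_MAP_NAMES, Mask3D, ParametricMap
from robustrad.features.discretize import discretize
from robustrad.features.firstorder import FIRSTORDER_NAMES, first_order_features
from robustrad.features.texture import TEXTURE_NAMES, texture_features

#: family -> ordered feature names; 18+24+16+16+5+14 = 93 per map
FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    **TEXTURE_NAMES,
}
N_FEATURES_PER_MAP = sum(len(v) for v in FEATURE_NAMES.values())


def feature_columns(map_names=ALL_MAP_NAMES) -> list[str]:
    """Canonical column order: map-major, family order within a map."""
    cols = []
    for m in map_names:
        for family, names in FEATURE_NAMES.items():
            cols.extend(f"{family}_{n}.{m}" for n in names)
    return cols


def extract_feature_vector(pmap: ParametricMap, mask: Mask3D, bin_width: float = 25.0) -> pd.Series:
    """The 93 features of one (map, ROI) pair, named ``family_Name.MAP``."""
    if pmap.data.shape != mask.data.shape:
        raise ValueError(
            f"map grid {pmap.data.shape} does not match mask grid {mask.data.shape}"
        )
    droi = discretize(pmap.data, mask.data, bin_width, spacing=pmap.spacing)
    vox_vol = float(np.prod(pmap.spacing))
    values = pmap.data[mask.data]
    out = {}
    fo = first_order_features(values, bin_width=bin_width, voxel_volume=vox_vol)
    for name in FIRSTORDER_NAMES:
        out[f"firstorder_{name}.{pmap.name}"] = fo[name]
    for family in TEXTURE_NAMES:
        vals = texture_features(droi, family)
        for name in TEXTURE_NAMES[family]:
            out[f"{family}_{name}.{pmap.name}"] = vals[name]
    s = pd.Series(out, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        bad = s.index[~np.isfinite(s.to_numpy())].tolist()
        raise ValueError(f"non-finite feature values for map {pmap.name}: {bad}")
    return s


def extract_features_for_maps(
    maps: dict[str, tuple[ParametricMap, Mask3D]],
    bin_widths: dict[str, float],
    expected_maps=ALL_MAP_NAMES,
) -> pd.Series:
    """Concatenate the 93-feature vectors of every expected map (1116 for 12)."""
    missing = [m for m in expected_maps if m not in maps]
    if missing:
        raise ValueError(f"missing parametric map(s): {missing}")
    parts = []
    for name in expected_maps:
        pmap, mask = maps[name]
        parts.append(extract_feature_vector(pmap, mask, bin_width=bin_widths[name]))
    return pd.concat(parts)


def extract_feature_table(
    records,
    bin_widths: dict[str, float],
    expected_maps=ALL_MAP_NAMES,
) -> pd.DataFrame:
    """Long-format cohort feature table.

    Parameters
    ----------
    records:
        Iterable of ``(lesion_id, roi_variant, maps)`` with ``maps`` a dict
        ``map_name -> (ParametricMap, Mask3D)``.

    Returns a DataFrame with ``lesion_id`` and ``roi_variant`` columns
    followed by the feature columns in canonical order (1116 for the full
    12-map set).
    """
    rows = []
    index = []
    for lesion_id, variant, maps in records:
        vec = extract_features_for_maps(maps, bin_widths, expected_maps=expected_maps)
        rows.append(vec)
        index.append((lesion_id, variant))
    table = pd.DataFrame(rows)
    table = table[feature_columns(expected_maps)]
    meta = pd.DataFrame(index, columns=["lesion_id", "roi_variant"])
    table = pd.concat([meta, table.reset_index(drop=True)], axis=1)
    return table
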