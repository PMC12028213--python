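"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` for volumes and ``(x, y, z, t)`` for
  dynamic series; voxel indices are 0-based and world coordinates follow
  the NIfTI affine ``diag(spacing)``.
* A DCE series carries frame times in seconds from the first (pre-contrast)
  acquisition; a DWI series carries b-values in s/mm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: the six model-free DCE descriptors, in canonical order
DCE_MODEL_FREE_NAMES = ("MRE", "TTP", "WIS", "WOS", "WOR", "WIO")
#: the three extended-Tofts maps
DCE_TOFTS_NAMES = ("KTRANS", "VE", "VP")
#: all nine DCE maps
DCE_MAP_NAMES = DCE_MODEL_FREE_NAMES + DCE_TOFTS_NAMES
#: the three IVIM maps
DWI_MAP_NAMES = ("D", "DSTAR", "F")
#: the full 12-map set a lesion contributes features from
ALL_MAP_NAMES = DCE_MAP_NAMES + DWI_MAP_NAMES


@dataclass
class DynamicSeries:
    """A 4D acquisition: 3D volumes stacked along time (DCE) or b-value (DWI).

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, n_frames)``.
    axis:
        Per-frame coordinate: seconds from the first frame for ``kind="dce"``,
        b-values in s/mm² for ``kind="dwi"``. Strictly increasing.
    spacing:
        Voxel size in mm per axis.
    """

    data: np.ndarray
    axis: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "dce"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.axis = np.asarray(self.axis, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D, got shape {self.data.shape}")
        if self.axis.ndim != 1 or self.axis.size != self.data.shape[3]:
            raise ValueError(
                f"axis length {self.axis.size} does not match "
                f"{self.data.shape[3]} frames"
            )
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("frame axis must be strictly increasing")
        if self.kind not in ("dce", "dwi"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three components")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class Mask3D:
    """A binary lesion mask on a series grid; the unit of ROI perturbation."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def barycenter(self) -> np.ndarray:
        """Center of mass in (fractional) voxel coordinates."""
        if self.voxel_count == 0:
            raise ValueError("empty mask has no barycenter")
        idx = np.nonzero(self.data)
        return np.array([np.mean(i) for i in idx])

    def border_margin(self) -> int:
        """Smallest distance (in voxels) from any mask voxel to the grid border."""
        if self.voxel_count == 0:
            raise ValueError("empty mask")
        idx = np.nonzero(self.data)
        margins = []
        for ax, ind in enumerate(idx):
            margins.append(ind.min())
            margins.append(self.data.shape[ax] - 1 - ind.max())
        return int(min(margins))

    def copy(self) -> "Mask3D":
        return Mask3D(self.data.copy(), self.spacing)


@dataclass
class ParametricMap:
    """One named 3D scalar map (NaN where a voxel was not computed or invalid)."""

    name: str
    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"map must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.name not in ALL_MAP_NAMES:
            raise ValueError(
                f"unknown map name {self.name!r}; expected one of {ALL_MAP_NAMES}"
            )
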