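"""Fixed-bin-width gray-level discretization of a masked map region.

level(v) = floor((v − min)/bin_width) + 1

anchored at the ROI minimum, so levels are consecutive positive integers
starting at 1. Texture matrices operate on the resulting integer array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_LEVELS = 65536  # guards against a pathological bin width


@dataclass
class DiscretizedROI:
    """Gray-level integer array over the ROI bounding box (0 = outside ROI)."""

    levels: np.ndarray          # 3D int array, cropped to the ROI bounding box
    mask: np.ndarray            # matching bool array (finite in-ROI voxels)
    n_levels: int
    bin_width: float
    value_range: tuple[float, float]
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def present_levels(self) -> np.ndarray:
        """Sorted distinct gray levels actually occurring in the ROI."""
        return np.unique(self.levels[self.mask])


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float,
               spacing=(1.0, 1.0, 1.0)) -> DiscretizedROI:
    """Discretize ``values`` inside ``mask`` with a fixed bin width.

    Non-finite voxels inside the mask are dropped from the effective ROI;
    an all-NaN (or empty) ROI raises.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    eff = mask & np.isfinite(values)
    if not eff.any():
        raise ValueError("no finite voxels inside the ROI")

    idx = np.nonzero(eff)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    v = values[box]
    m = eff[box]

    vmin = float(v[m].min())
    vmax = float(v[m].max())
    levels = np.zeros(v.shape, dtype=np.int64)
    levels[m] = np.floor((v[m] - vmin) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    if n_levels > MAX_LEVELS:
        raise ValueError(
            f"{n_levels} gray levels from bin_width={bin_width}; "
            "increase the bin width for this map"
        )
    return DiscretizedROI(
        levels=levels, mask=m, n_levels=n_levels, bin_width=float(bin_width),
        value_range=(vmin, vmax), spacing=tuple(float(s) for s in spacing),
    )
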