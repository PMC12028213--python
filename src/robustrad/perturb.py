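"""Artificial-ROI generation for segmentation-robustness screening.

From one manual (or phantom) lesion mask, fifteen perturbed variants are
generated to emulate inter-/intra-observer segmentation variability:

* six in-plane rotations (±10°, ±20°, ±30°) about the mask barycenter,
* two dilations (3D structuring elements of connectivity 1 and 2),
* one erosion (connectivity-1 element),
* six single-voxel translations (±x, ±y, ±z).

Rotation operates slice-wise in the axial (x, y) plane about the
projection of the 3D barycenter, with linear interpolation of the binary
mask re-thresholded at 0.5. A positive angle is counterclockwise in the
(x, y) index plane viewed from +z; the "clockwise" variants carry
negative angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from robustrad.core import Mask3D

VARIANT_NAMES = (
    "rot+10", "rot-10", "rot+20", "rot-20", "rot+30", "rot-30",
    "dil1", "dil2", "ero1",
    "tx+1", "tx-1", "ty+1", "ty-1", "tz+1", "tz-1",
)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class PerturbationSet:
    """The original mask plus its 15 named perturbed variants."""

    original: Mask3D
    variants: dict[str, Mask3D]
    provenance: dict[str, dict]

    def __post_init__(self) -> None:
        if tuple(self.variants) != VARIANT_NAMES:
            raise ValueError("expected exactly the 15 canonical variants, in order")
        for name, v in self.variants.items():
            if v.data.shape != self.original.data.shape:
                raise ValueError(f"variant {name} not on the original grid")
            if not v.data.any():
                raise ValueError(f"variant {name} is empty")


def rotate_mask(mask: Mask3D, angle_degrees: float) -> Mask3D:
    """In-plane rotation of the mask about its barycenter, slice by slice.

    The binary mask is linearly interpolated and re-binarized at 0.5.
    Raises if the rotated mask reaches the grid border (mass would exit).
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    cx, cy = mask.barycenter()[:2]
    theta = np.deg2rad(angle_degrees)
    c, s = np.cos(theta), np.sin(theta)
    # output voxel o takes the input value at R(-theta)(o - c) + c
    rot = np.array([[c, s], [-s, c]])
    offset = np.array([cx, cy]) - rot @ np.array([cx, cy])
    out = np.empty_like(mask.data, dtype=float)
    for k in range(mask.data.shape[2]):
        out[:, :, k] = ndimage.affine_transform(
            mask.data[:, :, k].astype(float), rot, offset=offset, order=1, cval=0.0
        )
    binary = out > 0.5
    if not binary.any():
        raise ValueError("rotation emptied the mask")
    rotated = Mask3D(binary, mask.spacing)
    if rotated.border_margin() == 0:
        raise ValueError("rotated mask exits the grid")
    return rotated


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 or 2")
    return ndimage.generate_binary_structure(3, connectivity)


def dilate_mask(mask: Mask3D, connectivity: int = 1) -> Mask3D:
    """One binary dilation with the 3D element of the given connectivity
    (1 = 6-neighbour cross, 2 = 18-neighbour)."""
    if not mask.data.any():
        raise ValueError("empty mask")
    return Mask3D(
        ndimage.binary_dilation(mask.data, structure=_structuring_element(connectivity)),
        mask.spacing,
    )


def erode_mask(mask: Mask3D) -> Mask3D:
    """One binary erosion with the connectivity-1 element."""
    if not mask.data.any():
        raise ValueError("empty mask")
    eroded = ndimage.binary_erosion(mask.data, structure=_structuring_element(1))
    if not eroded.any():
        raise ValueError(
            "erosion emptied the mask; lesions must exceed the structuring "
            "element (diameter >= 3 voxels along every axis)"
        )
    return Mask3D(eroded, mask.spacing)


def translate_mask(mask: Mask3D, axis: str, direction: int) -> Mask3D:
    """Rigid shift of every voxel by one voxel along ``axis`` (``direction`` ±1).

    Voxel count is preserved exactly; raises if the shift would push the
    mask out of the grid.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {tuple(_AXES)}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if not mask.data.any():
        raise ValueError("empty mask")
    ax = _AXES[axis]
    idx = np.nonzero(mask.data)[ax]
    n_ax = mask.data.shape[ax]
    if (direction == 1 and idx.max() == n_ax - 1) or (direction == -1 and idx.min() == 0):
        raise ValueError(f"translation {direction:+d} along {axis} exits the grid")
    shifted = np.roll(mask.data, direction, axis=ax)
    return Mask3D(shifted, mask.spacing)


def generate_artificial_rois(mask: Mask3D, margin_vox: int = 2) -> PerturbationSet:
    """The full set of 15 artificial ROIs (6 rotations, 2 dilations, 1 erosion,
    6 translations) from one mask with at least ``margin_vox`` voxels of
    border clearance."""
    if not mask.data.any():
        raise ValueError("empty mask")
    if mask.border_margin() < margin_vox:
        raise ValueError(
            f"mask needs a {margin_vox}-voxel margin from the grid border "
            f"(found {mask.border_margin()})"
        )
    variants: dict[str, Mask3D] = {}
    provenance: dict[str, dict] = {}

    def _run(name, fn, **params):
        try:
            variants[name] = fn()
        except ValueError as e:
            raise ValueError(f"variant {name}: {e}") from e
        provenance[name] = params

    for ang in (10, -10, 20, -20, 30, -30):
        _run(f"rot{ang:+d}", lambda a=ang: rotate_mask(mask, a),
             transform="rotate", angle_degrees=ang)
    _run("dil1", lambda: dilate_mask(mask, 1), transform="dilate", connectivity=1)
    _run("dil2", lambda: dilate_mask(mask, 2), transform="dilate", connectivity=2)
    _run("ero1", lambda: erode_mask(mask), transform="erode", connectivity=1)
    for axis in ("x", "y", "z"):
        for d in (1, -1):
            _run(f"t{axis}{d:+d}", lambda a=axis, dd=d: translate_mask(mask, a, dd),
                 transform="translate", axis=axis, direction=d)
    ordered = {name: variants[name] for name in VARIANT_NAMES}
    return PerturbationSet(original=mask, variants=ordered, provenance=provenance)


def union_of_variants(pset: PerturbationSet) -> Mask3D:
    """Union of the original mask and all 15 variants (the voxel support a
    parametric map must cover so every variant can be sampled)."""
    acc = pset.original.data.copy()
    for v in pset.variants.values():
        acc |= v.data
    return Mask3D(acc, pset.original.spacing)
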