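"""Synthetic DCE/DWI phantom cohorts with known ground truth.

Every downstream stage of the pipeline (mapping, perturbation, feature
extraction, robustness screening, classification) is exercised on
phantoms generated here: ellipsoidal lesions on a uniform background,
with per-lesion kinetic (extended Tofts) and diffusion (IVIM) parameters
drawn from class-dependent distributions for the three parotid tumor
classes — pleomorphic adenoma, Warthin tumor and malignant.

The acquisition emulates the study protocol: one pre-contrast plus ten
post-contrast DCE frames at 38 s temporal resolution, and DWI at eleven
b-values 0–800 s/mm². The default cohort is 15 adenomas, 10 Warthin and
18 malignant lesions (25 benign vs 18 malignant).

Signal models
-------------
* DCE: S(t) = S0·(1 + α·Ct(t)) in the lesion with Ct from the extended
  Tofts forward model, baseline-only background; additive Gaussian noise
  with sd = noise_sigma·S0 (default 2%).
* DWI: biexponential IVIM decay in the lesion; monoexponential
  background decay (healthy-parenchyma stand-in).

The class parameter distributions are deliberately well separated so the
end-to-end pipeline has a known recoverable signal; they are test
fixtures for the pipeline, not clinical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from robustrad.aif import WeinmannAIF
from robustrad.core import DynamicSeries, Mask3D
from robustrad.diffusion import ivim_signal
from robustrad.kinetic import tofts_forward

CLASS_LABELS = ("adenoma", "warthin", "malignant")

#: baseline (pre-contrast / b=0) signal in arbitrary units
BASELINE_SIGNAL = 100.0
#: monoexponential diffusion coefficient of the background tissue, mm^2/s
BACKGROUND_D = 1.0e-3


@dataclass
class AcquisitionSpec:
    """Acquisition timing, b-value set, grid geometry and noise level."""

    dce_n_frames: int = 11          # 1 pre-contrast + 10 post-contrast
    dce_dt: float = 38.0            # seconds per frame
    dwi_b_values: tuple = (0, 10, 20, 30, 50, 80, 100, 200, 300, 400, 800)
    grid_shape: tuple = (64, 64, 32)
    voxel_spacing: tuple = (1.0, 1.0, 3.0)   # mm
    noise_sigma: float = 0.02       # fraction of baseline signal

    def __post_init__(self) -> None:
        if self.dce_n_frames < 2:
            raise ValueError("need at least 2 DCE frames (1 pre + >=1 post)")
        b = np.asarray(self.dwi_b_values, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("b-values must start at 0 and be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def dce_times(self) -> np.ndarray:
        return np.arange(self.dce_n_frames) * self.dce_dt

    @property
    def b_values(self) -> np.ndarray:
        return np.asarray(self.dwi_b_values, dtype=float)


@dataclass
class LesionTruth:
    """Ground-truth parameters of one synthetic lesion (the recovery oracle)."""

    class_label: str
    ktrans: float       # min^-1
    ve: float           # fraction
    vp: float           # fraction
    d_true: float       # mm^2/s
    d_star: float       # mm^2/s
    f_perf: float       # fraction
    center: tuple       # voxel coordinates
    radii: tuple        # mm per axis

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")
        for name in ("ve", "vp", "f_perf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ve + self.vp > 1:
            raise ValueError("ve + vp must not exceed 1")
        if not self.d_star > self.d_true > 0:
            raise ValueError("require d_star > d_true > 0")
        if min(self.radii) < 5.0:
            raise ValueError("lesion radii must be >= 5 mm (diameter >= 1 cm)")


#: per-class (mean, sd) for each kinetic/diffusion parameter; chosen to be
#: realistic in scale and clearly separable between classes
DEFAULT_CLASS_DISTRIBUTIONS = {
    "adenoma": {
        "ktrans": (0.08, 0.02), "ve": (0.35, 0.05), "vp": (0.02, 0.008),
        "d_true": (1.6e-3, 1.2e-4), "d_star": (9e-3, 2e-3), "f_perf": (0.08, 0.02),
    },
    "warthin": {
        "ktrans": (0.50, 0.08), "ve": (0.12, 0.03), "vp": (0.04, 0.012),
        "d_true": (0.85e-3, 0.8e-4), "d_star": (14e-3, 3e-3), "f_perf": (0.25, 0.03),
    },
    "malignant": {
        "ktrans": (0.22, 0.08), "ve": (0.22, 0.06), "vp": (0.03, 0.012),
        "d_true": (0.95e-3, 1.0e-4), "d_star": (11e-3, 3e-3), "f_perf": (0.10, 0.03),
    },
}


@dataclass
class CohortSpec:
    """Cohort structure: class counts and parameter distributions."""

    n_per_class: dict = field(
        default_factory=lambda: {"adenoma": 15, "warthin": 10, "malignant": 18}
    )
    class_distributions: dict = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_CLASS_DISTRIBUTIONS.items()
        }
    )
    radii_range_mm: tuple = (5.0, 8.0)
    center_jitter_vox: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for c, n in self.n_per_class.items():
            if c not in CLASS_LABELS:
                raise ValueError(f"unknown class {c!r}")
            if n < 1:
                raise ValueError("class counts must be >= 1")
        for c, dists in self.class_distributions.items():
            for p, (_, sd) in dists.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {c}.{p}")


def make_lesion_mask(
    grid_shape: tuple,
    spacing: tuple,
    center: tuple,
    radii_mm: tuple,
    margin_vox: int = 2,
) -> Mask3D:
    """Ellipsoidal binary mask: a voxel is included iff its center lies inside.

    The ellipsoid must keep ``margin_vox`` voxels of clearance from every
    grid border so all fifteen ROI perturbations stay in bounds.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii_mm, dtype=float)
    r_vox = radii / spacing
    for ax in range(3):
        lo = center[ax] - r_vox[ax]
        hi = center[ax] + r_vox[ax]
        if lo < margin_vox or hi > grid_shape[ax] - 1 - margin_vox:
            raise ValueError(
                f"ellipsoid touches grid border along axis {ax} "
                f"(extent [{lo:.1f}, {hi:.1f}] on {grid_shape[ax]} voxels, "
                f"margin {margin_vox})"
            )
    coords = np.indices(grid_shape, dtype=float)
    q = sum(((coords[ax] - center[ax]) * spacing[ax] / radii[ax]) ** 2 for ax in range(3))
    return Mask3D(q <= 1.0, tuple(spacing))


def simulate_dce_series(
    truth: LesionTruth,
    acq: AcquisitionSpec,
    aif=None,
    seed: int = 0,
    alpha: float = 4.0,
) -> DynamicSeries:
    """Forward-simulate a DCE series for one lesion.

    Background voxels stay at baseline; lesion voxels follow
    S0·(1 + α·Ct(t)) with Ct from the extended-Tofts forward model; frame 0
    is pre-contrast. Gaussian noise (sd = noise_sigma·S0) is added
    independently per voxel and frame.
    """
    if aif is None:
        aif = WeinmannAIF()
    rng = np.random.default_rng(seed)
    times = acq.dce_times
    mask = make_lesion_mask(acq.grid_shape, acq.voxel_spacing, truth.center, truth.radii)
    ct = tofts_forward((truth.ktrans, truth.ve, truth.vp), aif, times)
    data = np.full(acq.grid_shape + (times.size,), BASELINE_SIGNAL, dtype=float)
    data[mask.data] = BASELINE_SIGNAL * (1.0 + alpha * ct)
    if acq.noise_sigma > 0:
        data += rng.normal(0.0, acq.noise_sigma * BASELINE_SIGNAL, size=data.shape)
    return DynamicSeries(data.astype(np.float32), times, acq.voxel_spacing, kind="dce")


def simulate_dwi_series(truth: LesionTruth, acq: AcquisitionSpec, seed: int = 0) -> DynamicSeries:
    """Forward-simulate a DWI series: IVIM decay in the lesion,
    monoexponential decay (coefficient ``BACKGROUND_D``) outside."""
    rng = np.random.default_rng(seed)
    b = acq.b_values
    mask = make_lesion_mask(acq.grid_shape, acq.voxel_spacing, truth.center, truth.radii)
    s_lesion = ivim_signal(b, BASELINE_SIGNAL, truth.d_true, truth.d_star, truth.f_perf)
    s_bg = BASELINE_SIGNAL * np.exp(-b * BACKGROUND_D)
    data = np.empty(acq.grid_shape + (b.size,), dtype=float)
    data[:] = s_bg
    data[mask.data] = s_lesion
    if acq.noise_sigma > 0:
        data += rng.normal(0.0, acq.noise_sigma * BASELINE_SIGNAL, size=data.shape)
    return DynamicSeries(data.astype(np.float32), b, acq.voxel_spacing, kind="dwi")


@dataclass
class SyntheticLesion:
    lesion_id: str
    truth: LesionTruth
    mask: Mask3D
    dce: DynamicSeries
    dwi: DynamicSeries
    seed: int


def _draw_truth(cls: str, spec: CohortSpec, acq: AcquisitionSpec, rng) -> LesionTruth:
    dists = spec.class_distributions[cls]
    grid = np.asarray(acq.grid_shape)
    for _ in range(100):
        p = {k: rng.normal(mu, sd) for k, (mu, sd) in dists.items()}
        center = grid / 2.0 + rng.integers(
            -spec.center_jitter_vox, spec.center_jitter_vox + 1, size=3
        )
        radii = rng.uniform(*spec.radii_range_mm, size=3)
        try:
            truth = LesionTruth(
                class_label=cls,
                ktrans=max(p["ktrans"], 1e-3),
                ve=float(np.clip(p["ve"], 1e-3, 1.0)),
                vp=float(np.clip(p["vp"], 0.0, 1.0)),
                d_true=p["d_true"],
                d_star=p["d_star"],
                f_perf=float(np.clip(p["f_perf"], 0.0, 1.0)),
                center=tuple(center),
                radii=tuple(radii),
            )
            # geometry must also respect the perturbation margin on this grid
            make_lesion_mask(acq.grid_shape, acq.voxel_spacing, truth.center,
                             truth.radii)
            return truth
        except ValueError:
            continue
    raise RuntimeError(f"could not draw a valid {cls} parameter set in 100 attempts")


def iter_cohort(spec: CohortSpec, acq: AcquisitionSpec, aif=None):
    """Yield the cohort one :class:`SyntheticLesion` at a time (streaming,
    so a full cohort never has to sit in memory at once). Deterministic
    given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    i = 0
    for cls in CLASS_LABELS:
        for _ in range(spec.n_per_class.get(cls, 0)):
            truth = _draw_truth(cls, spec, acq, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            mask = make_lesion_mask(
                acq.grid_shape, acq.voxel_spacing, truth.center, truth.radii
            )
            dce = simulate_dce_series(truth, acq, aif=aif, seed=seed)
            dwi = simulate_dwi_series(truth, acq, seed=seed + 1)
            yield SyntheticLesion(f"les{i:03d}", truth, mask, dce, dwi, seed)
            i += 1


def truth_row(lesion: SyntheticLesion) -> dict:
    t = lesion.truth
    return {
        "lesion_id": lesion.lesion_id, "class": t.class_label,
        "ktrans": t.ktrans, "ve": t.ve, "vp": t.vp,
        "d": t.d_true, "dstar": t.d_star, "f": t.f_perf,
        "seed": lesion.seed,
    }


def make_cohort(spec: CohortSpec, acq: AcquisitionSpec, aif=None):
    """Generate the full synthetic cohort in memory.

    Returns ``(lesions, truth_table)``: a list of :class:`SyntheticLesion`
    and a tidy DataFrame with one row per lesion (id, class,
    kinetic/diffusion truth, noise seed).
    """
    lesions = list(iter_cohort(spec, acq, aif=aif))
    return lesions, pd.DataFrame([truth_row(les) for les in lesions])
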