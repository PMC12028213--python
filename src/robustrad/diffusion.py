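"""Voxel-wise IVIM fitting of multi-b-value DWI.

Signal model (perfusion term carries its own pseudo-diffusion rate):

    S(b) = S0 · [ f·exp(−b·D*) + (1 − f)·exp(−b·D) ]

fitted with the classic segmented strategy: the true diffusion
coefficient D and the perfusion fraction f come from a log-linear fit of
the high-b regime (b ≥ b_split, default 200 s/mm², i.e. b ∈
{200,300,400,800} for the study b-set), after which D* is the only free
parameter in a 1-D bounded least-squares refinement on the full curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from robustrad.core import DynamicSeries, Mask3D, ParametricMap

B_SPLIT_DEFAULT = 200.0
#: parameter box (clipping outside it is flagged in QC)
D_BOUNDS = (1e-5, 4e-3)
DSTAR_MAX = 0.5


@dataclass
class IVIMParams:
    d: float        # mm^2/s
    d_star: float   # mm^2/s
    f: float        # fraction
    s0: float
    fit_rss: float = np.nan
    converged: bool = True
    clipped: bool = False


def ivim_signal(b: np.ndarray, s0: float, d: float, d_star: float, f: float) -> np.ndarray:
    """Forward biexponential IVIM signal."""
    b = np.asarray(b, dtype=float)
    return s0 * (f * np.exp(-b * d_star) + (1 - f) * np.exp(-b * d))


def fit_ivim(signal: np.ndarray, b_values: np.ndarray, b_split: float = B_SPLIT_DEFAULT) -> IVIMParams:
    """Segmented IVIM fit of one voxel's signal decay.

    Raises on non-positive signals, fewer than 4 distinct b-values, a
    missing b=0, or fewer than two b-values at/above ``b_split``.
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signal and b-values must align")
    if np.unique(b).size < 4:
        raise ValueError("need at least 4 distinct b-values")
    if b[0] != 0:
        raise ValueError("first b-value must be 0")
    if np.any(s <= 0):
        raise ValueError("non-positive signal encountered")
    hi = b >= b_split
    if hi.sum() < 2:
        raise ValueError(f"fewer than 2 b-values at or above b_split={b_split}")

    clipped = False
    s0 = float(s[0])

    def sse(d: float, d_star: float, f: float) -> float:
        r = ivim_signal(b, s0, d, d_star, f) - s
        return float(r @ r)

    # step 1: log-linear high-b fit -> D and, via the intercept, f;
    # step 2: 1-D bounded refinement of D* on the full biexponential.
    # The pair is iterated: once D* is known, the residual perfusion signal
    # still present at b >= b_split is subtracted before re-estimating D and
    # f, removing the bias of a single pass. Iteration stops as soon as the
    # correction is smaller than the fit's residual noise level - beyond
    # that point the "correction" only chases noise.
    d_star = None
    d = f = 0.0
    res_conv = True
    for _ in range(12):
        if d_star is None:
            s_hi = s[hi]
        else:
            correction = s0 * f * np.exp(-b[hi] * d_star)
            resid = ivim_signal(b, s0, d, d_star, f) - s
            sigma = np.sqrt((resid @ resid) / max(b.size - 4, 1))
            if correction.max() < sigma:
                break
            s_hi = s[hi] - correction
            if np.any(s_hi <= 0):  # over-correction: keep previous estimates
                break
        slope, intercept = np.polyfit(b[hi], np.log(s_hi), 1)
        d = float(np.clip(-slope, *D_BOUNDS))
        f = float(np.clip(1.0 - np.exp(intercept - np.log(s0)), 0.0, 1.0))
        if f <= 1e-6:
            # no perfusion compartment: D* unidentifiable, pinned to D
            d_star = d
            break
        res = minimize_scalar(
            lambda x: sse(d, x, f), bounds=(d, DSTAR_MAX), method="bounded",
            options={"xatol": 1e-8},
        )
        d_star = float(res.x)
        res_conv = bool(res.success)
    if d in D_BOUNDS or f in (0.0, 1.0):
        clipped = True
    return IVIMParams(
        d=float(d), d_star=float(d_star), f=float(f), s0=s0,
        fit_rss=sse(d, d_star, f), converged=res_conv, clipped=clipped,
    )


def _batched_ivim_fit(S: np.ndarray, b: np.ndarray, b_split: float = B_SPLIT_DEFAULT):
    """Vectorized iterated segmented fit over a (m, n_b) signal batch.

    Same algorithm as :func:`fit_ivim` (log-linear high-b stage for D and
    f, bounded 1-D search for D*, iterated with perfusion-signal
    subtraction); the D* search uses golden-section minimization so every
    voxel advances in lock-step. Returns (d, d_star, f, clipped) arrays.
    """
    m, _ = S.shape
    hi = b >= b_split
    b_hi = b[hi]
    bh_mean = b_hi.mean()
    bh_var = ((b_hi - bh_mean) ** 2).sum()
    s0 = S[:, 0]
    log_s0 = np.log(s0)

    d = np.zeros(m)
    f = np.zeros(m)
    d_star = np.full(m, np.nan)
    active = np.ones(m, dtype=bool)

    def sse_dstar(ds):
        sig = s0[:, None] * (
            f[:, None] * np.exp(-b[None, :] * ds[:, None])
            + (1 - f[:, None]) * np.exp(-b[None, :] * d[:, None])
        )
        return ((sig - S) ** 2).sum(axis=1)

    for it in range(12):
        if it == 0:
            s_corr = S[:, hi].copy()
        else:
            correction = (s0 * f)[:, None] * np.exp(-np.outer(d_star, b_hi))
            # adaptive stop: a correction below the residual noise level of
            # the current fit would only chase noise
            model = s0[:, None] * (
                f[:, None] * np.exp(-np.outer(d_star, b))
                + (1 - f[:, None]) * np.exp(-np.outer(d, b))
            )
            sigma = np.sqrt(((model - S) ** 2).sum(axis=1) / max(b.size - 4, 1))
            s_corr = S[:, hi] - correction
            overshoot = (s_corr <= 0).any(axis=1)
            below_noise = correction.max(axis=1) < sigma
            active &= ~(overshoot | below_noise)
        if not active.any():
            break
        logs = np.log(np.where(s_corr > 0, s_corr, 1.0))
        slope = ((b_hi - bh_mean)[None, :] * logs).sum(axis=1) / bh_var
        intercept = logs.mean(axis=1) - slope * bh_mean
        d_new = np.clip(-slope, *D_BOUNDS)
        f_new = np.clip(1.0 - np.exp(intercept - log_s0), 0.0, 1.0)
        d = np.where(active, d_new, d)
        f = np.where(active, f_new, f)
        # golden-section search for D* on [d, DSTAR_MAX]
        lo_i = d.copy()
        hi_i = np.full(m, DSTAR_MAX)
        invphi = (np.sqrt(5.0) - 1) / 2
        x1 = hi_i - invphi * (hi_i - lo_i)
        x2 = lo_i + invphi * (hi_i - lo_i)
        f1, f2 = sse_dstar(x1), sse_dstar(x2)
        for _ in range(45):
            take_left = f1 < f2  # minimum lies in [lo, x2]
            hi_new = np.where(take_left, x2, hi_i)
            lo_new = np.where(take_left, lo_i, x1)
            probe = np.where(
                take_left,
                hi_new - invphi * (hi_new - lo_new),
                lo_new + invphi * (hi_new - lo_new),
            )
            f_probe = sse_dstar(probe)
            x1, x2, f1, f2 = (
                np.where(take_left, probe, x2),
                np.where(take_left, x1, probe),
                np.where(take_left, f_probe, f2),
                np.where(take_left, f1, f_probe),
            )
            lo_i, hi_i = lo_new, hi_new
        ds_new = (lo_i + hi_i) / 2
        ds_new = np.where(f <= 1e-6, d, ds_new)
        d_star = np.where(active, ds_new, d_star)
    clipped = np.isin(d, D_BOUNDS) | np.isin(f, (0.0, 1.0))
    return d, d_star, f, clipped


def ivim_maps(series: DynamicSeries, mask: Mask3D) -> tuple[dict[str, ParametricMap], dict]:
    """The three IVIM maps {D, DSTAR, F} fitted per masked voxel, plus QC counts."""
    if series.kind != "dwi":
        raise ValueError("IVIM mapping requires a DWI series")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    b = series.axis
    S = series.data[m].astype(float)
    out = {name: np.full(S.shape[0], np.nan) for name in ("D", "DSTAR", "F")}
    valid = (S > 0).all(axis=1)
    n_invalid = int((~valid).sum())
    n_nonconv = 0
    if valid.any():
        d, d_star, f, clipped = _batched_ivim_fit(S[valid], b)
        out["D"][valid] = d
        out["DSTAR"][valid] = d_star
        out["F"][valid] = f
        n_clip = int(clipped.sum())
    else:
        n_clip = 0
    maps = {}
    for name, v in out.items():
        vol = np.full(series.grid_shape, np.nan)
        vol[m] = v
        maps[name] = ParametricMap(name, vol, series.spacing)
    qc = {
        "n_masked": int(m.sum()),
        "n_invalid_signal": n_invalid,
        "n_clipped": n_clip,
        "n_nonconverged": n_nonconv,
    }
    return maps, qc
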