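"""Voxel-wise DCE-MRI parametric mapping.

Six model-free descriptors of the relative-enhancement curve
E(t) = (S(t) − S0)/S0 and three extended-Tofts maps are computed per
voxel inside a lesion mask, yielding the nine DCE maps:

* MRE   — maximum relative enhancement, in % (max_t E(t) × 100)
* TTP   — time to peak, seconds from the first post-contrast frame
* WIS   — wash-in slope MRE/TTP, %/s (chord from baseline to peak)
* WOS   — wash-out slope (E_peak − E_last)/(t_last − t_peak) × 100, %/s
* WOR   — wash-out ratio (E_peak − E_last)/E_peak, dimensionless
* WIO   — wash-in over wash-out slope ratio WIS/WOS
* KTRANS, VE, VP — extended Tofts transfer constant (min⁻¹),
  extravascular-extracellular volume fraction and plasma volume fraction.

The Tofts fit operates on relative enhancement assumed proportional to
tissue concentration (E = α·Ct, α configurable), so no native T1 mapping
is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from robustrad.core import DynamicSeries, Mask3D, ParametricMap

# fixed multi-start initial points (ktrans, ve, vp) for the bounded fit
_TOFTS_STARTS = ((0.05, 0.2, 0.01), (0.3, 0.4, 0.05), (1.0, 0.6, 0.02))
_TOFTS_BOUNDS = ((0.0, 1e-3, 0.0), (3.0, 1.0, 1.0))

#: default cap substituted for WIO where the wash-out slope is zero
WIO_CAP_DEFAULT = 100.0


@dataclass
class EnhancementCurve:
    """Relative enhancement over time for one voxel; E(t0) = 0 by construction."""

    times: np.ndarray   # seconds from the first (pre-contrast) frame
    values: np.ndarray  # E(t), dimensionless
    s0: float           # pre-contrast signal


@dataclass
class ToftsParams:
    ktrans: float   # min^-1
    ve: float       # fraction
    vp: float       # fraction
    fit_rss: float = np.nan
    converged: bool = True


def enhancement_curve(series: DynamicSeries, voxel: tuple[int, int, int]) -> EnhancementCurve:
    """E(t) for one voxel. Raises if the pre-contrast signal is non-positive."""
    if series.kind != "dce":
        raise ValueError("enhancement curves are defined for DCE series")
    if series.n_frames < 2:
        raise ValueError("need at least two frames")
    s = np.asarray(series.data[voxel], dtype=float)
    s0 = float(s[0])
    if s0 <= 0:
        raise ValueError(f"non-positive pre-contrast signal ({s0}) at voxel {voxel}")
    return EnhancementCurve(times=series.axis.copy(), values=s / s0 - 1.0, s0=s0)


# ---------------------------------------------------------------------------
# model-free maps
# ---------------------------------------------------------------------------

def _model_free_from_curves(E: np.ndarray, times: np.ndarray, wio_cap: float):
    """Vectorized model-free descriptors from enhancement curves.

    Parameters
    ----------
    E:
        (n_voxels, n_frames) relative enhancement, frame 0 pre-contrast.
    times:
        Frame times in seconds from the first frame.
    """
    post = E[:, 1:]
    t_post = times[1:]
    dt_first = t_post[0] - times[0]
    # global maximum over post-contrast frames, ties broken by earliest time
    ipk = np.argmax(post, axis=1)
    e_pk = post[np.arange(post.shape[0]), ipk]
    t_pk = t_post[ipk]
    e_last = post[:, -1]
    t_last = t_post[-1]

    mre = e_pk * 100.0
    ttp = t_pk - t_post[0]
    # WIS = MRE/TTP; when the peak sits on the first post-contrast frame the
    # chord over one frame interval (MRE/dt) is used instead of dividing by 0
    wis = np.where(ttp > 0, mre / np.where(ttp > 0, ttp, 1.0), mre / dt_first)
    wis = np.where(mre > 0, wis, 0.0)
    at_last = ipk == post.shape[1] - 1
    denom = np.where(at_last, 1.0, t_last - t_pk)
    wos = np.where(at_last, 0.0, (e_pk - e_last) / denom * 100.0)
    # the raw ratio diverges when the peak is barely above baseline (pure
    # noise voxels); a wash-out ratio is a fraction of the peak lost, so it
    # is clipped to [0, 1] (values > 1 mean the signal fell below baseline)
    wor_raw = np.where(e_pk > 0, (e_pk - e_last) / np.where(e_pk > 0, e_pk, 1.0), 0.0)
    wor = np.clip(wor_raw, 0.0, 1.0)
    # WIO diverges as WOS -> 0+, so the cap clips the ratio as well as
    # replacing the undefined WOS = 0 case
    wio_raw = np.where(wos > 0, wis / np.where(wos > 0, wos, 1.0),
                       np.where(wis > 0, np.inf, 0.0))
    wio = np.minimum(wio_raw, wio_cap)
    qc = {"wio_capped": wio_raw > wio_cap, "wor_clipped": wor_raw != wor}
    return {"MRE": mre, "TTP": ttp, "WIS": wis, "WOS": wos, "WOR": wor, "WIO": wio}, qc


def model_free_maps(
    series: DynamicSeries,
    mask: Mask3D,
    wio_cap: float = WIO_CAP_DEFAULT,
) -> tuple[dict[str, ParametricMap], dict]:
    """The six model-free DCE maps inside ``mask``.

    Returns the maps (NaN outside the mask and at invalid voxels) and a QC
    dict with counts of invalid (S0 ≤ 0) and WIO-capped voxels.
    """
    if series.kind != "dce":
        raise ValueError("model-free maps require a DCE series")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    S = series.data[m].astype(float)          # (n_voxels, n_frames)
    s0 = S[:, 0]
    valid = s0 > 0
    if not valid.any():
        raise ValueError("all masked voxels have non-positive baseline signal")
    E = np.full_like(S, np.nan)
    E[valid] = S[valid] / s0[valid, None] - 1.0
    vals, curve_qc = _model_free_from_curves(E[valid], series.axis, wio_cap)

    maps = {}
    for name, v in vals.items():
        vol = np.full(series.grid_shape, np.nan)
        vv = np.full(valid.shape, np.nan)
        vv[valid] = v
        vol[m] = vv
        maps[name] = ParametricMap(name, vol, series.spacing)
    qc = {
        "n_masked": int(m.sum()),
        "n_invalid_s0": int((~valid).sum()),
        "n_wio_capped": int(curve_qc["wio_capped"].sum()),
        "n_wor_clipped": int(curve_qc["wor_clipped"].sum()),
        "wio_cap": float(wio_cap),
    }
    return maps, qc


# ---------------------------------------------------------------------------
# extended Tofts model
# ---------------------------------------------------------------------------

def tofts_forward(params, aif, times_s: np.ndarray) -> np.ndarray:
    """Extended-Tofts tissue concentration on a time grid.

    Ct(t) = Ktrans ∫₀ᵗ Cp(τ) e^{−(Ktrans/Ve)(t−τ)} dτ + Vp·Cp(t)

    ``params`` may be a :class:`ToftsParams` or a (ktrans, ve, vp) triple.
    For an AIF exposing exponential mixture terms the convolution is
    evaluated in closed form; otherwise a fine-grid numerical convolution
    is used.
    """
    if isinstance(params, ToftsParams):
        ktrans, ve, vp = params.ktrans, params.ve, params.vp
    else:
        ktrans, ve, vp = params
    times_s = np.asarray(times_s, dtype=float)
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve = 0 with ktrans > 0 leaves the rate constant undefined")

    cp = aif.cp(times_s)
    if ktrans == 0:
        return vp * cp
    kep = ktrans / ve  # min^-1

    if hasattr(aif, "exp_terms"):
        amps, rates = aif.exp_terms()
        u = np.clip(times_s - aif.onset_s, 0.0, None) / 60.0  # minutes
        conv = np.zeros_like(u)
        for a, mrate in zip(amps, rates):
            if abs(kep - mrate) < 1e-9:
                term = a * u * np.exp(-kep * u)
            else:
                term = a * (np.exp(-mrate * u) - np.exp(-kep * u)) / (kep - mrate)
            conv += term
        conv[times_s <= aif.onset_s] = 0.0
        return ktrans * conv + vp * cp

    # generic AIF: discrete convolution on a fine grid (trapezoid-corrected
    # endpoints), interpolated back to the acquisition times
    t_max = float(times_s.max())
    fine = np.linspace(0.0, t_max, max(2, int(t_max / 0.1) + 1))
    cp_fine = aif.cp(fine)
    dt_min = (fine[1] - fine[0]) / 60.0
    kern = np.exp(-kep * fine / 60.0)
    full = np.convolve(cp_fine, kern)[: fine.size]
    full -= 0.5 * (cp_fine * kern[0] + cp_fine[0] * kern)  # trapezoid ends
    ct_fine = ktrans * full * dt_min
    return np.interp(times_s, fine, ct_fine) + vp * cp


class _ToftsFitContext:
    """Precomputed quantities shared by every voxel fit on one time grid.

    Only valid for AIFs with exponential mixture terms (closed-form
    convolution and analytic Jacobian); the generic path falls back to
    :func:`tofts_forward` with a finite-difference Jacobian.
    """

    def __init__(self, aif, times_s: np.ndarray, alpha: float) -> None:
        self.aif = aif
        self.times_s = np.asarray(times_s, dtype=float)
        self.alpha = float(alpha)
        self.cp = aif.cp(self.times_s)
        self.analytic = hasattr(aif, "exp_terms")
        if self.analytic:
            amps, rates = aif.exp_terms()
            self.amps, self.rates = amps, rates
            self.u = np.clip(self.times_s - aif.onset_s, 0.0, None) / 60.0
            self.pre = self.times_s <= aif.onset_s
            self.Ei = np.exp(-np.outer(rates, self.u))  # (n_terms, n_t)

    def model_and_jac(self, theta):
        ktrans, ve, vp = theta
        if not self.analytic:
            ct = tofts_forward(theta, self.aif, self.times_s)
            return self.alpha * ct, None
        kep = ktrans / ve
        u, Ek = self.u, np.exp(-kep * np.clip(self.times_s - self.aif.onset_s, 0, None) / 60.0)
        conv = np.zeros_like(u)
        dconv = np.zeros_like(u)  # d conv / d kep
        for a, m, Ei in zip(self.amps, self.rates, self.Ei):
            dk = kep - m
            if abs(dk) < 1e-9:
                conv += a * u * Ek
                dconv += -a * u**2 * Ek
            else:
                conv += a * (Ei - Ek) / dk
                dconv += a * (u * Ek * dk - (Ei - Ek)) / dk**2
        conv[self.pre] = 0.0
        dconv[self.pre] = 0.0
        ct = ktrans * conv + vp * self.cp
        d_ktrans = conv + ktrans * dconv / ve
        d_ve = ktrans * dconv * (-ktrans / ve**2)
        jac = self.alpha * np.stack([d_ktrans, d_ve, self.cp], axis=1)
        return self.alpha * ct, jac


def _fit_tofts_with_context(ctx: _ToftsFitContext, y: np.ndarray) -> ToftsParams:
    def residual(theta):
        model, _ = ctx.model_and_jac(theta)
        return model - y

    def jacobian(theta):
        _, jac = ctx.model_and_jac(theta)
        return jac

    kwargs = {"jac": jacobian} if ctx.analytic else {}
    best = None
    for x0 in _TOFTS_STARTS:
        try:
            res = least_squares(
                residual, x0, bounds=_TOFTS_BOUNDS, method="trf",
                xtol=1e-9, ftol=1e-9, gtol=1e-9, max_nfev=40, **kwargs,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ToftsParams(0.0, 1e-3, 0.0, np.inf, converged=False)
    k, ve, vp = best.x
    return ToftsParams(
        float(k), float(ve), float(vp),
        fit_rss=float(2 * best.cost),
        converged=bool(best.status > 0),
    )


def fit_tofts_curve(
    curve_E: np.ndarray,
    times_s: np.ndarray,
    aif,
    alpha: float = 1.0,
) -> ToftsParams:
    """Bounded nonlinear least-squares fit of α·Ct(t;θ) to one enhancement curve.

    Multi-start from three fixed initial points; deterministic and seed-free.
    """
    ctx = _ToftsFitContext(aif, times_s, alpha)
    return _fit_tofts_with_context(ctx, np.asarray(curve_E, dtype=float))


# ---------------------------------------------------------------------------
# batched fitting (all masked voxels at once)
# ---------------------------------------------------------------------------

def _batch_model_jac(ctx: _ToftsFitContext, theta: np.ndarray):
    """Model curves and Jacobians for a (m, 3) parameter batch."""
    kt, ve, vp = theta[:, 0], theta[:, 1], theta[:, 2]
    kep = kt / ve
    u = ctx.u[None, :]
    with np.errstate(over="ignore", under="ignore"):
        Ek = np.exp(-kep[:, None] * u)
    conv = np.zeros_like(Ek)
    dconv = np.zeros_like(Ek)
    for a, m, Ei in zip(ctx.amps, ctx.rates, ctx.Ei):
        dk = kep - m
        safe = np.abs(dk) >= 1e-9
        dk_safe = np.where(safe, dk, 1.0)[:, None]
        num = Ei[None, :] - Ek
        conv += np.where(
            safe[:, None], a * num / dk_safe, a * u * Ek
        )
        dconv += np.where(
            safe[:, None],
            a * (u * Ek * dk_safe - num) / dk_safe**2,
            -a * u**2 * Ek,
        )
    conv[:, ctx.pre] = 0.0
    dconv[:, ctx.pre] = 0.0
    model = ctx.alpha * (kt[:, None] * conv + vp[:, None] * ctx.cp[None, :])
    d_kt = conv + (kt / ve)[:, None] * dconv
    d_ve = (-(kt**2) / ve**2)[:, None] * dconv
    d_vp = np.broadcast_to(ctx.cp[None, :], model.shape)
    jac = ctx.alpha * np.stack([d_kt, d_ve, d_vp], axis=2)
    return model, jac


def _batched_tofts_fit(ctx: _ToftsFitContext, Y: np.ndarray, max_iter: int = 60):
    """Box-projected Levenberg-Marquardt over all voxels simultaneously.

    Same model, bounds and three fixed starting points as the scalar fit;
    the per-voxel best-of-starts solution is returned as
    ``(params (m, 3), rss (m,))``.
    """
    lo = np.asarray(_TOFTS_BOUNDS[0])
    hi = np.asarray(_TOFTS_BOUNDS[1])
    m = Y.shape[0]
    best_theta = np.zeros((m, 3))
    best_cost = np.full(m, np.inf)
    for x0 in _TOFTS_STARTS:
        theta = np.tile(np.asarray(x0, dtype=float), (m, 1))
        model, _ = _batch_model_jac(ctx, theta)
        cost = ((model - Y) ** 2).sum(axis=1)
        lam = np.full(m, 1e-3)
        for _ in range(max_iter):
            model, jac = _batch_model_jac(ctx, theta)
            r = model - Y
            g = np.einsum("mtj,mt->mj", jac, r)
            H = np.einsum("mti,mtj->mij", jac, jac)
            Haug = H.copy()
            idx = np.arange(3)
            Haug[:, idx, idx] += lam[:, None] * H[:, idx, idx] + 1e-12
            try:
                delta = -np.linalg.solve(Haug, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                Haug[:, idx, idx] += 1e-6
                delta = -np.linalg.solve(Haug, g[..., None])[..., 0]
            cand = np.clip(theta + delta, lo, hi)
            model_c, _ = _batch_model_jac(ctx, cand)
            cost_c = ((model_c - Y) ** 2).sum(axis=1)
            improved = cost_c < cost
            theta = np.where(improved[:, None], cand, theta)
            cost = np.where(improved, cost_c, cost)
            lam = np.clip(np.where(improved, lam * 0.3, lam * 4.0), 1e-10, 1e12)
        better = cost < best_cost
        best_theta[better] = theta[better]
        best_cost[better] = cost[better]
    return best_theta, best_cost


def fit_tofts_maps(
    series: DynamicSeries,
    mask: Mask3D,
    aif,
    alpha: float = 1.0,
) -> tuple[dict[str, ParametricMap], dict]:
    """Voxel-wise extended-Tofts maps {KTRANS, VE, VP} inside ``mask``."""
    if series.kind != "dce":
        raise ValueError("Tofts fitting requires a DCE series")
    if series.n_frames < 3:
        raise ValueError("need at least two post-contrast frames")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    times = series.axis
    S = series.data[m].astype(float)
    s0 = S[:, 0]
    valid = s0 > 0
    out = {name: np.full(S.shape[0], np.nan) for name in ("KTRANS", "VE", "VP")}
    ctx = _ToftsFitContext(aif, times, alpha)
    vidx = np.nonzero(valid)[0]
    if ctx.analytic:
        E = S[vidx] / s0[vidx, None] - 1.0
        theta, _ = _batched_tofts_fit(ctx, E)
        out["KTRANS"][vidx] = theta[:, 0]
        out["VE"][vidx] = theta[:, 1]
        out["VP"][vidx] = theta[:, 2]
        n_nonconv = 0
    else:
        n_nonconv = 0
        for i in vidx:
            p = _fit_tofts_with_context(ctx, S[i] / s0[i] - 1.0)
            if not p.converged:
                n_nonconv += 1
            out["KTRANS"][i] = p.ktrans
            out["VE"][i] = p.ve
            out["VP"][i] = p.vp
    maps = {}
    for name, v in out.items():
        vol = np.full(series.grid_shape, np.nan)
        vol[m] = v
        maps[name] = ParametricMap(name, vol, series.spacing)
    qc = {
        "n_masked": int(m.sum()),
        "n_invalid_s0": int((~valid).sum()),
        "n_nonconverged": n_nonconv,
    }
    return maps, qc
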