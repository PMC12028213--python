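"""Texture-matrix families: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

Conventions (stated because implementations in the wild differ):

* GLCM and GLRLM use the 13 unique 3D direction offsets; the
  co-occurrence matrix is symmetric; features are computed per direction
  and averaged (directions with no voxel pairs are skipped).
* GLSZM zones, NGTDM neighbourhoods and GLDM dependencies all use
  26-connectivity.
* Gray-level weights in the formulas are the actual discretized level
  values; matrices are stored over the levels present in the ROI, and
  Ng (where a formula normalizes by it) is the number of distinct levels
  present.
* GLDM dependence size counts the center voxel plus its in-mask
  26-neighbours within |level difference| <= alpha (alpha = 0), so a
  fully isolated voxel has dependence 1.
* Entropy-style sums run over non-zero probabilities with log base 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: the 13 unique 3D direction offsets (one per antipodal pair)
OFFSETS_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

#: all 26 neighbour offsets
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
TEXTURE_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

COARSENESS_CAP = 1e6


class DegenerateROIError(ValueError):
    """The ROI is too small for this texture family (e.g. a single voxel
    has no voxel pairs for the GLCM and no neighbours for the NGTDM)."""


def _pair_views(arr: np.ndarray, off):
    """Aligned views (center, neighbour-at-+off) of a 3D array."""
    sl_a, sl_b = [], []
    for d, n in zip(off, arr.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(droi) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction.

    Returns ``(P, g)``: P of shape (13, Ng, Ng) over the Ng present
    levels g (sorted ascending).
    """
    g = droi.present_levels
    ng = g.size
    rank = np.zeros(droi.n_levels + 1, dtype=np.int64)
    rank[g] = np.arange(ng)
    L = np.where(droi.mask, droi.levels, 0)
    P = np.zeros((len(OFFSETS_13), ng, ng), dtype=float)
    for k, off in enumerate(OFFSETS_13):
        a, b = _pair_views(L, off)
        sel = (a > 0) & (b > 0)
        if not sel.any():
            continue
        ra, rb = rank[a[sel]], rank[b[sel]]
        counts = np.bincount(ra * ng + rb, minlength=ng * ng).reshape(ng, ng)
        P[k] = counts + counts.T
    return P, g.astype(float)


def _glcm_single(P: np.ndarray, g: np.ndarray, ng_total: int) -> dict[str, float]:
    """All 24 GLCM features for one normalized co-occurrence matrix."""
    p = P / P.sum()
    gi = g[:, None]
    gj = g[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((g * px).sum())
    uy = float((g * py).sum())
    sx = float(np.sqrt((((g - ux) ** 2) * px).sum()))
    sy = float(np.sqrt((((g - uy) ** 2) * py).sum()))

    gint = g.astype(np.int64)
    ksum = (gint[:, None] + gint[None, :]).ravel()
    p_sum = np.bincount(ksum, weights=p.ravel())
    ks = np.arange(p_sum.size, dtype=float)
    kdiff = np.abs(gint[:, None] - gint[None, :]).ravel()
    p_diff = np.bincount(kdiff, weights=p.ravel())
    kd = np.arange(p_diff.size, dtype=float)

    da = float((kd * p_diff).sum())
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    pq = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pq[nz])).sum())
    hxy2 = _entropy(pq.ravel())

    if sx > 0 and sy > 0:
        corr = float(((p * gi * gj).sum() - ux * uy) / (sx * sy))
    else:
        corr = 1.0
    imc1 = float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2 * (hxy2 - hxy)))) if hxy2 > hxy else 0.0

    # MCC: second-largest eigenvalue of Q over levels with marginal mass
    act = px > 0
    if act.sum() <= 1:
        mcc = 1.0
    else:
        pa = p[np.ix_(act, act)]
        pxa, pya = px[act], py[act]
        Q = (pa / pxa[:, None]) @ (pa / pya[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0))) if ev.size > 1 else 1.0

    ng = float(ng_total)
    return {
        "Autocorrelation": float((p * gi * gj).sum()),
        "ClusterProminence": float((p * (gi + gj - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (gi + gj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (gi + gj - ux - uy) ** 2).sum()),
        "Contrast": float((p * (gi - gj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float((p_diff * (kd - da) ** 2).sum()),
        "Id": float((p_diff / (1 + kd)).sum()),
        "Idm": float((p_diff / (1 + kd**2)).sum()),
        "Idmn": float((p_diff / (1 + (kd / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1 + kd / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / kd[1:] ** 2).sum()),
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((p * (gi - ux) ** 2).sum()),
    }


def glcm_features(droi) -> dict[str, float]:
    P, g = glcm_matrices(droi)
    totals = P.sum(axis=(1, 2))
    if not (totals > 0).any():
        raise DegenerateROIError("no voxel pairs: GLCM undefined (single-voxel ROI)")
    ng_total = g.size
    acc: dict[str, float] = {name: 0.0 for name in GLCM_NAMES}
    n_dir = 0
    for k in range(P.shape[0]):
        if totals[k] == 0:
            continue
        for name, val in _glcm_single(P[k], g, ng_total).items():
            acc[name] += val
        n_dir += 1
    return {name: acc[name] / n_dir for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(droi) -> tuple[list[np.ndarray], np.ndarray]:
    """Run-length count matrices (one per direction) over present levels.

    Each matrix has shape (Ng, Lmax) with column l-1 counting maximal runs
    of length l.
    """
    g = droi.present_levels
    ng = g.size
    rank = np.zeros(droi.n_levels + 1, dtype=np.int64)
    rank[g] = np.arange(ng)
    L = np.where(droi.mask, droi.levels, 0)
    diag = int(np.ceil(np.sqrt(sum(n**2 for n in L.shape)))) + 1
    mats = []
    for off in OFFSETS_13:
        R = np.zeros((ng, diag), dtype=float)
        # run ends: voxels whose +off neighbour differs (or is outside)
        nxt = np.zeros_like(L)
        a, b = _pair_views(nxt, off)
        a_src, b_src = _pair_views(L, off)
        a[...] = b_src  # value of the +off neighbour, 0 at the boundary
        is_end = (L > 0) & (L != nxt)
        # walk backwards along -off counting chain length
        chain = is_end.copy()
        length = 1
        while chain.any() and length <= diag:
            # voxels in `chain` are run ends whose backward chain spans at
            # least `length` voxels; the chain extends iff the voxel
            # `length` steps back along -off carries the same level
            shift_val = np.zeros_like(L)
            sa, sb = _pair_views(shift_val, tuple(-d * length for d in off))
            va, vb = _pair_views(L, tuple(-d * length for d in off))
            sa[...] = vb
            extend = chain & (shift_val == L)
            finish = chain & ~extend
            if finish.any():
                lv = rank[L[finish]]
                np.add.at(R, (lv, length - 1), 1)
            chain = extend
            length += 1
        mats.append(R)
    return mats, g.astype(float)


def _glrlm_single(R: np.ndarray, g: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    lengths = np.arange(1, R.shape[1] + 1, dtype=float)
    gi = g[:, None]
    li = lengths[None, :]
    pg = R.sum(axis=1)
    pl = R.sum(axis=0)
    p = R / nr
    mu_g = (g * pg / nr).sum()
    mu_l = (lengths * pl / nr).sum()
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * pg / nr).sum()),
        "HighGrayLevelRunEmphasis": float((R * gi**2).sum() / nr),
        "LongRunEmphasis": float((R * li**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * gi**2 * li**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * li**2 / gi**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((R / gi**2).sum() / nr),
        "RunEntropy": _entropy(p.ravel()),
        "RunLengthNonUniformity": float((pl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float((((lengths - mu_l) ** 2) * pl / nr).sum()),
        "ShortRunEmphasis": float((R / li**2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * gi**2 / li**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (gi**2 * li**2)).sum() / nr),
    }


def glrlm_features(droi) -> dict[str, float]:
    mats, g = glrlm_matrices(droi)
    acc = {name: 0.0 for name in GLRLM_NAMES}
    n_dir = 0
    for R in mats:
        if R.sum() == 0:
            continue
        for name, val in _glrlm_single(R, g, droi.n_voxels).items():
            acc[name] += val
        n_dir += 1
    if n_dir == 0:
        raise DegenerateROIError("empty ROI: GLRLM undefined")
    return {name: acc[name] / n_dir for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(droi) -> tuple[np.ndarray, np.ndarray]:
    """Size-zone count matrix over present levels; zones are 26-connected
    components of equal gray level."""
    g = droi.present_levels
    ng = g.size
    L = np.where(droi.mask, droi.levels, 0)
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level = []
    max_size = 1
    for lev in g:
        lab, n = ndimage.label(L == lev, structure=structure)
        if n == 0:
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((ng, max_size), dtype=float)
    for i, sizes in enumerate(sizes_per_level):
        for s in sizes:
            Z[i, s - 1] += 1
    return Z, g.astype(float)


def glszm_features(droi) -> dict[str, float]:
    Z, g = glszm_matrix(droi)
    nz = Z.sum()
    if nz == 0:
        raise DegenerateROIError("empty ROI: GLSZM undefined")
    sizes = np.arange(1, Z.shape[1] + 1, dtype=float)
    gi = g[:, None]
    si = sizes[None, :]
    pg = Z.sum(axis=1)
    ps = Z.sum(axis=0)
    p = Z / nz
    mu_g = (g * pg / nz).sum()
    mu_s = (sizes * ps / nz).sum()
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * pg / nz).sum()),
        "HighGrayLevelZoneEmphasis": float((Z * gi**2).sum() / nz),
        "LargeAreaEmphasis": float((Z * si**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((Z * gi**2 * si**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((Z * si**2 / gi**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((Z / gi**2).sum() / nz),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "SmallAreaEmphasis": float((Z / si**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((Z * gi**2 / si**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((Z / (gi**2 * si**2)).sum() / nz),
        "ZoneEntropy": _entropy(p.ravel()),
        "ZonePercentage": float(nz / droi.n_voxels),
        "ZoneVariance": float((((sizes - mu_s) ** 2) * ps / nz).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(droi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level counts n_i and summed absolute gray-tone differences s_i.

    For each ROI voxel, the difference is |level − mean level of its
    in-mask 26-neighbours|; voxels with no in-mask neighbour are excluded.
    Returns (g, n, s) over present levels.
    """
    L = np.where(droi.mask, droi.levels, 0)
    nb_sum = np.zeros(L.shape, dtype=float)
    nb_cnt = np.zeros(L.shape, dtype=float)
    for off in OFFSETS_26:
        a_sum, _ = _pair_views(nb_sum, off)
        a_cnt, _ = _pair_views(nb_cnt, off)
        _, b = _pair_views(L, off)
        a_sum += b
        a_cnt += b > 0
    valid = (L > 0) & (nb_cnt > 0)
    if not valid.any():
        raise DegenerateROIError("no voxel has in-ROI neighbours: NGTDM undefined")
    diff = np.abs(L[valid] - nb_sum[valid] / nb_cnt[valid])
    lv = L[valid]
    g = droi.present_levels
    n = np.zeros(g.size, dtype=float)
    s = np.zeros(g.size, dtype=float)
    for i, lev in enumerate(g):
        sel = lv == lev
        n[i] = sel.sum()
        s[i] = diff[sel].sum()
    return g.astype(float), n, s


def ngtdm_features(droi) -> dict[str, float]:
    g, n, s = ngtdm_table(droi)
    nvp = n.sum()
    p = n / nvp
    present = p > 0
    gp, pp, sp = g[present], p[present], s[present]
    ngp = int(present.sum())

    coarse_den = float((pp * sp).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else COARSENESS_CAP

    if ngp > 1:
        contrast = float(
            (pp[:, None] * pp[None, :] * (gp[:, None] - gp[None, :]) ** 2).sum()
            / (ngp * (ngp - 1))
            * sp.sum() / nvp
        )
        busy_den = float(np.abs(gp[:, None] * pp[:, None] - gp[None, :] * pp[None, :]).sum())
        busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(gp[:, None] - gp[None, :])
             * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum() / nvp
        )
        s_total = float(sp.sum())
        strength = float(
            ((pp[:, None] + pp[None, :]) * (gp[:, None] - gp[None, :]) ** 2).sum()
            / s_total
        ) if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": float(min(coarseness, COARSENESS_CAP)),
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(droi, alpha: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Dependence count matrix P(i, j) over present levels.

    j = 1 + number of in-mask 26-neighbours with |level difference| <= alpha.
    """
    g = droi.present_levels
    ng = g.size
    rank = np.zeros(droi.n_levels + 1, dtype=np.int64)
    rank[g] = np.arange(ng)
    L = np.where(droi.mask, droi.levels, 0)
    dep = np.zeros(L.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, _ = _pair_views(dep, off)
        ca, cb = _pair_views(L, off)
        a += (cb > 0) & (np.abs(ca - cb) <= alpha)
    dep = np.where(L > 0, dep + 1, 0)
    jmax = int(dep.max())
    P = np.zeros((ng, jmax), dtype=float)
    sel = L > 0
    np.add.at(P, (rank[L[sel]], dep[sel] - 1), 1)
    return P, g.astype(float)


def gldm_features(droi, alpha: int = 0) -> dict[str, float]:
    P, g = gldm_matrix(droi, alpha=alpha)
    nz = P.sum()
    if nz == 0:
        raise DegenerateROIError("empty ROI: GLDM undefined")
    deps = np.arange(1, P.shape[1] + 1, dtype=float)
    gi = g[:, None]
    ji = deps[None, :]
    pg = P.sum(axis=1)
    pj = P.sum(axis=0)
    p = P / nz
    mu_g = (g * pg / nz).sum()
    mu_j = (deps * pj / nz).sum()
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float((pj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj**2).sum() / nz**2),
        "DependenceVariance": float((((deps - mu_j) ** 2) * pj / nz).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * pg / nz).sum()),
        "HighGrayLevelEmphasis": float((P * gi**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * ji**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * gi**2 * ji**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * ji**2 / gi**2).sum() / nz),
        "LowGrayLevelEmphasis": float((P / gi**2).sum() / nz),
        "SmallDependenceEmphasis": float((P / ji**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * gi**2 / ji**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (gi**2 * ji**2)).sum() / nz),
    }


_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def texture_features(droi, family: str) -> dict[str, float]:
    """All features of one texture family for a discretized ROI."""
    try:
        fn = _FAMILY_FUNCS[family]
    except KeyError:
        raise ValueError(f"unknown texture family {family!r}") from None
    return fn(droi)
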