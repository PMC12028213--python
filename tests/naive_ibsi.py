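"""Independent, loop-based oracle for the 93 radiomic features.

Everything here is computed with explicit Python loops and dictionaries,
directly transcribing the gray-level matrix definitions (same stated
conventions as the package: 13 directions for GLCM/GLRLM with
per-direction feature averaging, 26-connectivity for GLSZM zones, NGTDM
neighbourhoods and GLDM dependencies, level weights = actual level
values, Ng = number of levels present). It deliberately shares no code
with the package implementation so the two can serve as mutual checks.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def naive_discretize(values, mask, bin_width):
    """dict voxel -> level, over finite masked voxels."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    voxels = [
        tuple(v) for v in np.argwhere(mask)
        if math.isfinite(values[tuple(v)])
    ]
    vmin = min(values[v] for v in voxels)
    return {v: int(math.floor((values[v] - vmin) / bin_width)) + 1 for v in voxels}


def _entropy(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


def naive_firstorder(values, mask, bin_width, voxel_volume):
    x = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    x = x[np.isfinite(x)]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p50, p75, p90 = (np.percentile(x, q) for q in (10, 25, 50, 75, 90))
    hist = {}
    for v in x:
        lev = int(math.floor((v - min(x)) / bin_width))
        hist[lev] = hist.get(lev, 0) + 1
    probs = [c / n for c in hist.values()]
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    energy = sum(v**2 for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": _entropy(probs),
        "Minimum": min(x),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": max(x),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": max(x) - min(x),
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (sum(abs(v - rmean) for v in robust) / len(robust)) if robust else 0.0,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p**2 for p in probs),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_counts(lev, direction):
    counts = {}
    for (x, y, z), a in lev.items():
        nb = (x + direction[0], y + direction[1], z + direction[2])
        if nb in lev:
            b = lev[nb]
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def _glcm_single(counts, levels_present):
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    g = sorted({i for i, _ in p} | {j for _, j in p})
    px = {i: sum(p.get((i, j), 0) for j in g) for i in g}
    py = {j: sum(p.get((i, j), 0) for i in g) for j in g}
    ux = sum(i * px[i] for i in g)
    uy = sum(j * py[j] for j in g)
    sx = math.sqrt(sum((i - ux) ** 2 * px[i] for i in g))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j] for j in g))
    psum, pdiff = {}, {}
    for (i, j), v in p.items():
        psum[i + j] = psum.get(i + j, 0) + v
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0) + v
    da = sum(k * v for k, v in pdiff.items())
    hxy = _entropy(p.values())
    hx = _entropy(px.values())
    hy = _entropy(py.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = _entropy([px[i] * py[j] for i in g for j in g])
    ng = len(levels_present)

    if sx > 0 and sy > 0:
        corr = (sum(i * j * v for (i, j), v in p.items()) - ux * uy) / (sx * sy)
    else:
        corr = 1.0

    act = [i for i in g if px[i] > 0]
    if len(act) <= 1:
        mcc = 1.0
    else:
        Q = np.zeros((len(act), len(act)))
        for a_i, i in enumerate(act):
            for a_j, j in enumerate(act):
                Q[a_i, a_j] = sum(
                    p.get((i, k), 0) * p.get((j, k), 0) / (px[i] * py[k])
                    for k in act
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(max(ev[1], 0.0))

    return {
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "ClusterProminence": sum((i + j - ux - uy) ** 4 * v for (i, j), v in p.items()),
        "ClusterShade": sum((i + j - ux - uy) ** 3 * v for (i, j), v in p.items()),
        "ClusterTendency": sum((i + j - ux - uy) ** 2 * v for (i, j), v in p.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(v / (1 + k) for k, v in pdiff.items()),
        "Idm": sum(v / (1 + k**2) for k, v in pdiff.items()),
        "Idmn": sum(v / (1 + (k / ng) ** 2) for k, v in pdiff.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in pdiff.items()),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(1 - math.exp(-2 * (hxy2 - hxy))) if hxy2 > hxy else 0.0,
        "InverseVariance": sum(v / k**2 for k, v in pdiff.items() if k >= 1),
        "JointAverage": ux,
        "JointEnergy": sum(v**2 for v in p.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": _entropy(psum.values()),
        "SumSquares": sum((i - ux) ** 2 * v for (i, j), v in p.items()),
    }


def naive_glcm(lev):
    present = sorted(set(lev.values()))
    per_dir = []
    for d in DIRECTIONS:
        counts = _glcm_counts(lev, d)
        if counts:
            per_dir.append(_glcm_single(counts, present))
    if not per_dir:
        raise ValueError("no voxel pairs")
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs(lev, direction):
    runs = {}
    for v, level in lev.items():
        prev = tuple(v[i] - direction[i] for i in range(3))
        if lev.get(prev) == level:
            continue  # not a run start
        length = 1
        nxt = tuple(v[i] + direction[i] for i in range(3))
        while lev.get(nxt) == level:
            length += 1
            nxt = tuple(nxt[i] + direction[i] for i in range(3))
        runs[(level, length)] = runs.get((level, length), 0) + 1
    return runs


def _glrlm_single(runs, n_voxels):
    nr = sum(runs.values())
    pg, pl = {}, {}
    for (g, l), c in runs.items():
        pg[g] = pg.get(g, 0) + c
        pl[l] = pl.get(l, 0) + c
    mu_g = sum(g * c for g, c in pg.items()) / nr
    mu_l = sum(l * c for l, c in pl.items()) / nr
    return {
        "GrayLevelNonUniformity": sum(c**2 for c in pg.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in pg.values()) / nr**2,
        "GrayLevelVariance": sum((g - mu_g) ** 2 * c for g, c in pg.items()) / nr,
        "HighGrayLevelRunEmphasis": sum(g**2 * c for (g, l), c in runs.items()) / nr,
        "LongRunEmphasis": sum(l**2 * c for (g, l), c in runs.items()) / nr,
        "LongRunHighGrayLevelEmphasis": sum(g**2 * l**2 * c for (g, l), c in runs.items()) / nr,
        "LongRunLowGrayLevelEmphasis": sum(l**2 / g**2 * c for (g, l), c in runs.items()) / nr,
        "LowGrayLevelRunEmphasis": sum(c / g**2 for (g, l), c in runs.items()) / nr,
        "RunEntropy": _entropy([c / nr for c in runs.values()]),
        "RunLengthNonUniformity": sum(c**2 for c in pl.values()) / nr,
        "RunLengthNonUniformityNormalized": sum(c**2 for c in pl.values()) / nr**2,
        "RunPercentage": nr / n_voxels,
        "RunVariance": sum((l - mu_l) ** 2 * c for l, c in pl.items()) / nr,
        "ShortRunEmphasis": sum(c / l**2 for (g, l), c in runs.items()) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(g**2 / l**2 * c for (g, l), c in runs.items()) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(c / (g**2 * l**2) for (g, l), c in runs.items()) / nr,
    }


def naive_glrlm(lev):
    per_dir = [_glrlm_single(_runs(lev, d), len(lev)) for d in DIRECTIONS]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def _zones(lev):
    seen = set()
    zones = {}
    for start, level in lev.items():
        if start in seen:
            continue
        # flood fill over 26-connected same-level voxels
        stack, comp = [start], set()
        seen.add(start)
        comp.add(start)
        while stack:
            v = stack.pop()
            for d in NEIGHBOURS_26:
                nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if nb not in comp and lev.get(nb) == level:
                    comp.add(nb)
                    seen.add(nb)
                    stack.append(nb)
        zones[(level, len(comp))] = zones.get((level, len(comp)), 0) + 1
    return zones


def naive_glszm(lev):
    zones = _zones(lev)
    nz = sum(zones.values())
    pg, ps = {}, {}
    for (g, s), c in zones.items():
        pg[g] = pg.get(g, 0) + c
        ps[s] = ps.get(s, 0) + c
    mu_g = sum(g * c for g, c in pg.items()) / nz
    mu_s = sum(s * c for s, c in ps.items()) / nz
    return {
        "GrayLevelNonUniformity": sum(c**2 for c in pg.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in pg.values()) / nz**2,
        "GrayLevelVariance": sum((g - mu_g) ** 2 * c for g, c in pg.items()) / nz,
        "HighGrayLevelZoneEmphasis": sum(g**2 * c for (g, s), c in zones.items()) / nz,
        "LargeAreaEmphasis": sum(s**2 * c for (g, s), c in zones.items()) / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(g**2 * s**2 * c for (g, s), c in zones.items()) / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(s**2 / g**2 * c for (g, s), c in zones.items()) / nz,
        "LowGrayLevelZoneEmphasis": sum(c / g**2 for (g, s), c in zones.items()) / nz,
        "SizeZoneNonUniformity": sum(c**2 for c in ps.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(c**2 for c in ps.values()) / nz**2,
        "SmallAreaEmphasis": sum(c / s**2 for (g, s), c in zones.items()) / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(g**2 / s**2 * c for (g, s), c in zones.items()) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(c / (g**2 * s**2) for (g, s), c in zones.items()) / nz,
        "ZoneEntropy": _entropy([c / nz for c in zones.values()]),
        "ZonePercentage": nz / len(lev),
        "ZoneVariance": sum((s - mu_s) ** 2 * c for s, c in ps.items()) / nz,
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def naive_ngtdm(lev):
    n_i, s_i = {}, {}
    for v, level in lev.items():
        nbs = [
            lev[(v[0] + d[0], v[1] + d[1], v[2] + d[2])]
            for d in NEIGHBOURS_26
            if (v[0] + d[0], v[1] + d[1], v[2] + d[2]) in lev
        ]
        if not nbs:
            continue
        n_i[level] = n_i.get(level, 0) + 1
        s_i[level] = s_i.get(level, 0) + abs(level - sum(nbs) / len(nbs))
    if not n_i:
        raise ValueError("no voxel has neighbours")
    nvp = sum(n_i.values())
    p = {g: c / nvp for g, c in n_i.items()}
    gs = sorted(p)
    ngp = len(gs)
    den = sum(p[g] * s_i[g] for g in gs)
    coarseness = min(1 / den, 1e6) if den > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in gs for j in gs)
            / (ngp * (ngp - 1)) * sum(s_i.values()) / nvp
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in gs for j in gs)
        busyness = den / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in gs for j in gs
        ) / nvp
        s_tot = sum(s_i.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in gs for j in gs) / s_tot
            if s_tot > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def naive_gldm(lev, alpha=0):
    table = {}
    for v, level in lev.items():
        dep = 1
        for d in NEIGHBOURS_26:
            nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if nb in lev and abs(lev[nb] - level) <= alpha:
                dep += 1
        table[(level, dep)] = table.get((level, dep), 0) + 1
    nz = sum(table.values())
    pg, pj = {}, {}
    for (g, j), c in table.items():
        pg[g] = pg.get(g, 0) + c
        pj[j] = pj.get(j, 0) + c
    mu_g = sum(g * c for g, c in pg.items()) / nz
    mu_j = sum(j * c for j, c in pj.items()) / nz
    return {
        "DependenceEntropy": _entropy([c / nz for c in table.values()]),
        "DependenceNonUniformity": sum(c**2 for c in pj.values()) / nz,
        "DependenceNonUniformityNormalized": sum(c**2 for c in pj.values()) / nz**2,
        "DependenceVariance": sum((j - mu_j) ** 2 * c for j, c in pj.items()) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in pg.values()) / nz,
        "GrayLevelVariance": sum((g - mu_g) ** 2 * c for g, c in pg.items()) / nz,
        "HighGrayLevelEmphasis": sum(g**2 * c for (g, j), c in table.items()) / nz,
        "LargeDependenceEmphasis": sum(j**2 * c for (g, j), c in table.items()) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(g**2 * j**2 * c for (g, j), c in table.items()) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(j**2 / g**2 * c for (g, j), c in table.items()) / nz,
        "LowGrayLevelEmphasis": sum(c / g**2 for (g, j), c in table.items()) / nz,
        "SmallDependenceEmphasis": sum(c / j**2 for (g, j), c in table.items()) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(g**2 / j**2 * c for (g, j), c in table.items()) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(c / (g**2 * j**2) for (g, j), c in table.items()) / nz,
    }


def naive_feature_vector(values, mask, bin_width, voxel_volume=1.0):
    """All 93 features keyed ``family_Name`` (no map suffix)."""
    lev = naive_discretize(values, mask, bin_width)
    out = {}
    for name, v in naive_firstorder(values, mask, bin_width, voxel_volume).items():
        out[f"firstorder_{name}"] = v
    for family, fn in (
        ("glcm", naive_glcm), ("glrlm", naive_glrlm), ("glszm", naive_glszm),
        ("ngtdm", naive_ngtdm), ("gldm", naive_gldm),
    ):
        for name, v in fn(lev).items():
            out[f"{family}_{name}"] = v
    return out
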