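"""The 18 first-order (intensity histogram and moment) features.

Entropy and Uniformity operate on the fixed-bin-width discretized
histogram of the ROI; all other features use the raw voxel values.
Skewness is the standardized third population moment; Kurtosis is the
(non-excess) fourth standardized moment, so a Gaussian scores ≈ 3.
Both are defined as 0 for a constant region.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(
    values: np.ndarray,
    bin_width: float = 25.0,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """All 18 first-order features of a set of ROI voxel values."""
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values in ROI")
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized histogram for entropy / uniformity
    lev = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(lev).astype(float) / n
    p = p[p > 0]

    robust = x[(x >= p10) & (x <= p90)]
    # tiny ROIs can leave the 10th-90th percentile band empty
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float((x**2).sum())
    out = {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float((p**2).sum()),
    }
    return out
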