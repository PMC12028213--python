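"""Feature reproducibility across ROI perturbations, scored with the ICC.

Each feature's values over (lesions × ROI variants) form a two-way
layout: lesions are the "subjects", the 16 ROI variants (original + 15
perturbations) the "raters". Reproducibility is the two-way
random-effects, absolute-agreement, single-measurement ICC — ICC(2,1) —

    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

from the mean squares of the two-way ANOVA decomposition (n subjects,
k raters). Absolute agreement is the appropriate form here because a
systematic offset introduced by a perturbation (e.g. dilation diluting a
lesion with background) is a real reproducibility failure, not a
rater "style" to be forgiven.

Agreement categories follow the conventional thresholds: below 0.5 poor,
0.5–0.75 moderate, 0.75–0.9 good, above 0.9 excellent; only features
with ICC strictly greater than 0.9 enter the robust set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ICC_THRESHOLD_DEFAULT = 0.9
CATEGORY_EDGES = (0.5, 0.75, 0.9)


def icc(matrix: np.ndarray) -> float:
    """ICC(2,1) of one subjects × raters matrix.

    A matrix with zero total variance is defined as perfect agreement
    (ICC = 1). Negative estimates are returned as computed.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("missing cells are not supported")
    return float(icc_many(m[None, ...])[0])


def icc_many(stack: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over a (m, n_subjects, k_raters) stack."""
    x = np.asarray(stack, dtype=float)
    _, n, k = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    row = x.mean(axis=2, keepdims=True)
    col = x.mean(axis=1, keepdims=True)
    ssr = (k * (row - grand) ** 2).sum(axis=(1, 2))
    ssc = (n * (col - grand) ** 2).sum(axis=(1, 2))
    sst = ((x - grand) ** 2).sum(axis=(1, 2))
    sse = np.clip(sst - ssr - ssc, 0.0, None)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    # zero total variance: every cell identical -> trivially perfect agreement
    scale = np.maximum(np.abs(x).max(axis=(1, 2)) ** 2, 1.0)
    trivial = sst <= 1e-12 * scale
    safe = np.abs(denom) > 0
    out = np.where(safe, (msr - mse) / np.where(safe, denom, 1.0), 0.0)
    out[trivial] = 1.0
    return out


def categorize(value: float) -> str:
    """Agreement category for one ICC value (negatives are 'poor')."""
    if value > CATEGORY_EDGES[2]:
        return "excellent"
    if value >= CATEGORY_EDGES[1]:
        return "good"
    if value >= CATEGORY_EDGES[0]:
        return "moderate"
    return "poor"


def robust_feature_set(
    table: pd.DataFrame,
    threshold: float = ICC_THRESHOLD_DEFAULT,
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature ICC across ROI variants and the strict ICC > threshold gate.

    Parameters
    ----------
    table:
        Long-format feature table with ``lesion_id`` and ``roi_variant``
        columns; every lesion must carry the identical variant set.

    Returns
    -------
    (robust_features, report):
        The retained feature names and a report DataFrame with columns
        feature, map, icc, category, n_subjects, n_raters.
    """
    feature_cols = [c for c in table.columns if c not in ("lesion_id", "roi_variant")]
    lesions = table["lesion_id"].unique()
    variants = table["roi_variant"].unique()
    counts = table.groupby("lesion_id")["roi_variant"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != len(variants):
        raise ValueError("unbalanced ROI-variant coverage across lesions")
    n, k = len(lesions), len(variants)

    wide = table.set_index(["lesion_id", "roi_variant"])[feature_cols]
    # stack: (features, subjects, raters)
    stack = (
        wide.to_numpy().reshape(n, k, len(feature_cols)).transpose(2, 0, 1)
    )
    values = icc_many(stack)
    report = pd.DataFrame({
        "feature": feature_cols,
        "map": [c.rsplit(".", 1)[1] for c in feature_cols],
        "icc": values,
        "category": [categorize(v) for v in values],
        "n_subjects": n,
        "n_raters": k,
    })
    robust = report.loc[report["icc"] > threshold, "feature"].tolist()
    return robust, report


def icc_matrix_report(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot the ICC report into a features × maps matrix (heatmap layout)."""
    rep = report.copy()
    rep["base"] = [f.rsplit(".", 1)[0] for f in rep["feature"]]
    return rep.pivot(index="base", columns="map", values="icc")
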