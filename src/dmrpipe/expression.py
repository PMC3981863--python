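"""Two-group microarray expression screen and related expression utilities.

The screen mirrors the classic single-channel workflow: log2 transform,
75th-percentile shift normalization, per-probe two-sample Student's t-test,
Benjamini-Hochberg correction, and a joint fold-change/q-value gate
(|FC| > 2, q < 0.05 by default).  Also provided: average-linkage
hierarchical clustering of samples on 1 - Pearson correlation, and
delta-delta-Ct relative expression for qPCR-style data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "percentile_shift_normalize",
    "bh_adjust",
    "two_group_screen",
    "hierarchical_cluster",
    "qpcr_relative_expression",
]


def percentile_shift_normalize(
    matrix: pd.DataFrame, percentile: float = 75, input_scale: str = "linear"
) -> pd.DataFrame:
    """Log2-transform and shift each sample so its given percentile aligns
    to the across-sample median of those percentiles.

    With ``input_scale="linear"`` (the default) intensities must be strictly
    positive and are log2-transformed first; with ``input_scale="log2"`` the
    matrix is taken as already log-scale.  Output is always on the log2
    scale, and after normalization all samples share the same value at
    ``percentile``.  The shift is idempotent: re-normalizing the output
    (as log2 data) changes nothing.
    """
    values = matrix.to_numpy(dtype=float)
    if input_scale == "linear":
        if not np.all(values > 0):
            raise ValueError(
                "intensities must be strictly positive for log2 transform"
            )
        log2 = np.log2(values)
    elif input_scale == "log2":
        log2 = values
    else:
        raise ValueError(f"unknown input_scale: {input_scale!r}")
    per_sample = np.percentile(log2, percentile, axis=0)
    target = np.median(per_sample)
    shifted = log2 - per_sample[np.newaxis, :] + target
    return pd.DataFrame(shifted, index=matrix.index, columns=matrix.columns)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m/j) p_(j) on the sorted p-values, mapped back to
    the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _student_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    # zero pooled variance: p = 1 when means are equal, 0 when they differ
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    return t, p


def two_group_screen(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-probe differential-expression verdicts between two sample groups.

    ``matrix`` holds log2-scale normalized values (probes x samples).  For
    each probe: log2 fold change = mean(A) - mean(B), two-sample t-test
    (pooled variance by default, Welch with ``equal_var=False``), BH
    adjustment across all probes, then status:

    * ``up``   — log2FC >  log2(fc_threshold) and q < q_threshold
    * ``down`` — log2FC < -log2(fc_threshold) and q < q_threshold
    * ``not_significant`` otherwise

    "up" means higher in ``group_a``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >=2 samples for a t-test")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = _student_t(a, b, equal_var)
    q = bh_adjust(p)
    lfc_gate = np.abs(log2_fc) > np.log2(fc_threshold)
    sig = lfc_gate & (q < q_threshold)
    status = np.where(sig, np.where(log2_fc > 0, "up", "down"), "not_significant")
    return pd.DataFrame(
        {
            "probe": matrix.index,
            "log2_fold_change": log2_fc,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).set_index("probe")


def hierarchical_cluster(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Returns the scipy linkage matrix and the sample labels in input (leaf
    index) order.  A zero-variance sample profile makes the correlation
    undefined and raises a ValueError naming the sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering requires >=2 samples")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=0)
    for name, sd in zip(matrix.columns, sds):
        if sd == 0:
            raise ValueError(
                f"sample {name!r} has zero variance: correlation undefined"
            )
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return linkage, list(matrix.columns)


def qpcr_relative_expression(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    calibrator_samples: list[str],
) -> pd.Series:
    """Delta-delta-Ct relative expression.

    Per sample: level = 2^-(Ct_target - Ct_reference), then all levels are
    divided by the mean level of ``calibrator_samples`` so the calibrator
    group averages exactly 1.
    """
    if not calibrator_samples:
        raise ValueError("calibrator_samples must be non-empty")
    ct_target = ct_target.astype(float)
    ct_reference = ct_reference.astype(float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise ValueError("Ct values must be finite")
    levels = np.power(2.0, -(ct_target - ct_reference))
    return levels / levels.loc[calibrator_samples].mean()
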