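"""Pyrosequencing-style CpG methylation summaries and group comparisons.

Data arrive as a tidy table of per-CpG methylation percentages per clone.
The clone — not the CpG — is the statistical unit: CpG values are first
averaged within each clone at a locus, then clone means are summarized per
group (mean, sample SD) and compared between groups with a pooled-variance
two-sample t-test.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "validate_methylation_table",
    "summarize_methylation",
    "compare_methylation",
    "read_methylation_table",
]

REQUIRED_COLUMNS = ("clone_id", "group", "locus", "cpg_index", "methylation_pct")


def validate_methylation_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"methylation table missing columns: {missing}")
    pct = table["methylation_pct"].astype(float)
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("methylation_pct values must lie in [0, 100]")
    if table.duplicated(subset=["clone_id", "locus", "cpg_index"]).any():
        raise ValueError("(clone_id, locus, cpg_index) rows must be unique")
    return table


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    return validate_methylation_table(pd.read_csv(path, sep="\t"))


def clone_means(table: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Per-clone mean methylation across CpGs at one locus."""
    sub = table[table["locus"] == locus]
    if sub.empty:
        raise ValueError(f"locus {locus!r} absent from methylation table")
    return (
        sub.groupby(["group", "clone_id"])["methylation_pct"]
        .mean()
        .rename("clone_mean")
        .reset_index()
    )


def summarize_methylation(table: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n of clone means at ``locus``.

    A single-clone group has no defined sample SD; it is reported as 0.0
    and flagged via ``n = 1``.
    """
    means = clone_means(validate_methylation_table(table), locus)
    out = (
        means.groupby("group")["clone_mean"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    out.insert(0, "locus", locus)
    return out


def compare_methylation(
    table: pd.DataFrame, locus: str, group_a: str, group_b: str
) -> tuple[float, float]:
    """Pooled-variance t-test on clone means between two groups.

    Returns ``(t_statistic, p_value)``; identical groups give t=0, p=1.
    """
    means = clone_means(validate_methylation_table(table), locus)
    a = means.loc[means["group"] == group_a, "clone_mean"].to_numpy()
    b = means.loc[means["group"] == group_b, "clone_mean"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 clones for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if a.var() == 0 and b.var() == 0:
        equal = a.mean() == b.mean()
        t, p = (0.0, 1.0) if equal else (float(t), 0.0)
    return float(t), float(p)
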