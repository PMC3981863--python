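"""Replicate-concordance proportions between biological replicates.

The concordance of two peak sets is the number of regions (from both
samples) overlapping at least one region of the other sample, divided by
the total number of regions detected in the two samples.  Identical samples
score 1.0; disjoint samples score 0.0.  A region overlapping several regions
of the other sample is counted once (presence, not pairing).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd

from .intervals import RegionSet, overlap_filter

__all__ = ["ConcordancePair", "pairwise_concordance", "concordance_matrix"]


class UndefinedConcordanceError(ValueError):
    """Both samples are empty: the proportion has no defined value."""


@dataclass(frozen=True)
class ConcordancePair:
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int

    @property
    def proportion(self) -> float:
        return (self.n_a_overlapping + self.n_b_overlapping) / (self.n_a + self.n_b)


def pairwise_concordance(
    a: RegionSet, b: RegionSet, min_overlap: int = 1
) -> ConcordancePair:
    """Two-sided overlap proportion between two replicate region sets."""
    if len(a) + len(b) == 0:
        raise UndefinedConcordanceError(
            f"both samples empty ({a.sample_id}, {b.sample_id}): "
            "concordance proportion undefined"
        )
    return ConcordancePair(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping=len(overlap_filter(a, b, min_overlap)),
        n_b_overlapping=len(overlap_filter(b, a, min_overlap)),
    )


def concordance_matrix(
    samples: Sequence[RegionSet], min_overlap: int = 1
) -> pd.DataFrame:
    """All unordered-pair concordances as a tidy table.

    Columns: sample_a, sample_b, n_a, n_b, n_overlap_a, n_overlap_b,
    proportion.  Symmetric by construction.
    """
    if len(samples) < 2:
        raise ValueError("concordance_matrix requires >=2 samples")
    rows = []
    for a, b in combinations(samples, 2):
        pair = pairwise_concordance(a, b, min_overlap)
        rows.append(
            {
                "sample_a": pair.sample_a,
                "sample_b": pair.sample_b,
                "n_a": pair.n_a,
                "n_b": pair.n_b,
                "n_overlap_a": pair.n_a_overlapping,
                "n_overlap_b": pair.n_b_overlapping,
                "proportion": pair.proportion,
            }
        )
    return pd.DataFrame(rows)
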