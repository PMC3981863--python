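"""Genomic interval data model, BED3+ I/O and interval-set primitives.

Coordinates are 0-based half-open (BED convention) throughout the package.
A :class:`RegionSet` is one sample's methylated regions: intervals are merged
and sorted at construction so that "number of regions" is well defined.
Chromosome names are compared as exact strings (no "chr" aliasing).
"""

from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "BedParseError",
    "merge",
    "intersect_bases",
    "overlap_filter",
    "read_bed",
    "write_bed",
]


class BedParseError(ValueError):
    """Raised when a BED data line cannot be parsed into a valid interval."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Sort and merge intervals, joining any pair separated by <= ``gap`` bp.

    The union of covered bases is preserved (for gap=0).  Input may be
    unsorted, overlapping or duplicated.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


@dataclass(frozen=True)
class RegionSet:
    """A per-sample collection of sorted, merged genomic intervals."""

    sample_id: str
    cell_type: str
    intervals: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(merge(self.intervals)))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        return {
            chrom: list(ivs)
            for chrom, ivs in itertools.groupby(self.intervals, key=lambda iv: iv.chrom)
        }

    def replace(self, intervals: Iterable[GenomicInterval]) -> "RegionSet":
        return RegionSet(self.sample_id, self.cell_type, tuple(intervals))


def intersect_bases(
    a: RegionSet | Sequence[GenomicInterval],
    b: RegionSet | Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Merged intervals covering exactly the bases covered by both inputs.

    Two-pointer sweep per chromosome; commutative; for merged inputs the
    output is itself merged.
    """
    ivs_a = merge(a.intervals if isinstance(a, RegionSet) else a)
    ivs_b = merge(b.intervals if isinstance(b, RegionSet) else b)
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(ivs_a) and j < len(ivs_b):
        x, y = ivs_a[i], ivs_b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        # advance whichever interval ends first
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return merge(out)


def _has_overlap(
    iv: GenomicInterval,
    subject_by_chrom: dict[str, tuple[list[int], list[GenomicInterval]]],
    min_overlap: int,
) -> bool:
    entry = subject_by_chrom.get(iv.chrom)
    if entry is None:
        return False
    starts, ivs = entry
    # first subject interval that could overlap: the one before the insertion
    # point of iv.start may still extend across it
    k = bisect_left(starts, iv.start)
    if k > 0:
        k -= 1
    for s in ivs[k:]:
        if s.start >= iv.end:
            break
        if iv.overlap_length(s) >= min_overlap:
            return True
    return False


def overlap_filter(
    query: RegionSet, subject: RegionSet, min_overlap: int = 1
) -> RegionSet:
    """Keep query intervals overlapping >= ``min_overlap`` bp with at least
    one subject interval (bedtools ``intersect -u`` presence semantics).

    Query interval coordinates are returned unmodified.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be a positive integer")
    subject_idx = {
        chrom: ([iv.start for iv in ivs], ivs)
        for chrom, ivs in subject.by_chrom().items()
    }
    kept = [
        iv for iv in query.intervals if _has_overlap(iv, subject_idx, min_overlap)
    ]
    return query.replace(kept)


def read_bed(
    path: str | Path, sample_id: str | None = None, cell_type: str = ""
) -> RegionSet:
    """Read a BED3+ file into a merged :class:`RegionSet`.

    '#'-comment, 'track' and 'browser' lines are skipped; columns beyond the
    third are ignored.  Malformed coordinates raise :class:`BedParseError`
    naming the offending line; an empty file yields an empty set.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end} "
                    "(require 0 <= start < end)"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(sample_id, cell_type, tuple(intervals))


def write_bed(
    regions: RegionSet | Sequence[GenomicInterval], path: str | Path
) -> None:
    """Write sorted BED3 (tab-separated, 0-based half-open)."""
    ivs = regions.intervals if isinstance(regions, RegionSet) else sorted(regions)
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
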