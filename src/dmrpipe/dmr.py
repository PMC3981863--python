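"""Consensus building and DMR/CMR classification between two cell types.

The comparison follows the presence/absence logic of replicate-consensus
MBD-seq analysis:

1. Per cell type, build a *consensus set*: the base-pair intersection of all
   replicates' methylated regions, so every consensus base is supported by
   every replicate.
2. Test each consensus region for presence (>= ``min_overlap`` bp overlap)
   in each sample of the other cell type, one by one.

   * present in **no** other-type sample  -> **DMR** (cell-type specific)
   * present in **all** other-type samples -> **CMR** (commonly methylated)
   * present in some but not all           -> **PARTIAL**

3. CMR regions found from both directions describe the same shared
   methylation, so the two CMR lists are unified by coordinate union and
   counted once.  PARTIAL regions are retained for inspection but excluded
   from the reported totals and percentages, which therefore cover exactly
   DMR-A + DMR-B + CMR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Sequence

from .intervals import (
    GenomicInterval,
    RegionSet,
    intersect_bases,
    merge,
    overlap_filter,
    write_bed,
)

__all__ = [
    "ConsensusSet",
    "RegionLabel",
    "ComparisonResult",
    "build_consensus",
    "classify_against",
    "compare_cell_types",
    "summarize_comparison",
    "round_half_up",
]

Label = Literal["DMR", "CMR", "PARTIAL"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 4.45 -> 4.5), used by the report layer."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConsensusSet:
    """Regions whose every base is covered by all replicates of one type."""

    cell_type: str
    regions: tuple[GenomicInterval, ...]
    n_replicates: int

    def __len__(self) -> int:
        return len(self.regions)

    def as_region_set(self, sample_id: str | None = None) -> RegionSet:
        return RegionSet(
            sample_id or f"{self.cell_type}_consensus", self.cell_type, self.regions
        )


@dataclass(frozen=True)
class RegionLabel:
    region: GenomicInterval
    label: Label
    n_other_supporting: int


@dataclass(frozen=True)
class ComparisonResult:
    cell_type_a: str
    cell_type_b: str
    dmr_a: RegionSet
    dmr_b: RegionSet
    cmr: RegionSet
    partial_a: RegionSet
    partial_b: RegionSet

    @property
    def n_total(self) -> int:
        return len(self.dmr_a) + len(self.dmr_b) + len(self.cmr)

    @property
    def percentages(self) -> tuple[float, float, float]:
        return summarize_comparison(len(self.dmr_a), len(self.dmr_b), self.n_total)

    @property
    def pct_dmr_a(self) -> float:
        return self.percentages[0]

    @property
    def pct_dmr_b(self) -> float:
        return self.percentages[1]

    @property
    def pct_cmr(self) -> float:
        return self.percentages[2]

    def summary_dict(self) -> dict:
        if self.n_total == 0:
            pct_a = pct_b = pct_cmr = None
        else:
            pct_a, pct_b, pct_cmr = self.percentages
        return {
            "cell_type_a": self.cell_type_a,
            "cell_type_b": self.cell_type_b,
            "n_dmr_a": len(self.dmr_a),
            "n_dmr_b": len(self.dmr_b),
            "n_cmr": len(self.cmr),
            "n_partial_a": len(self.partial_a),
            "n_partial_b": len(self.partial_b),
            "n_total": self.n_total,
            "pct_dmr_a": None if pct_a is None else round_half_up(pct_a, 1),
            "pct_dmr_b": None if pct_b is None else round_half_up(pct_b, 1),
            "pct_cmr": None if pct_cmr is None else round_half_up(pct_cmr, 1),
        }

    def write(self, outdir: str | Path) -> None:
        """Write per-category BED files, a summary JSON and a region table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        named = {
            "dmr_a": self.dmr_a,
            "dmr_b": self.dmr_b,
            "cmr": self.cmr,
            "partial_a": self.partial_a,
            "partial_b": self.partial_b,
        }
        for name, rs in named.items():
            write_bed(rs, outdir / f"{name}.bed")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
            fh.write("\n")
        with open(outdir / "regions.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tlabel\n")
            for name, rs in named.items():
                for iv in rs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def build_consensus(
    samples: Sequence[RegionSet], cell_type: str | None = None
) -> ConsensusSet:
    """Base-pair intersection of all replicates of one cell type.

    With a single sample the consensus is that sample's intervals.  All
    samples must carry the same ``cell_type`` label (or pass one explicitly).
    """
    if not samples:
        raise ValueError("build_consensus requires at least one sample")
    labels = {s.cell_type for s in samples}
    if cell_type is None:
        if len(labels) > 1:
            raise ValueError(f"mixed cell_type labels in replicates: {sorted(labels)}")
        cell_type = samples[0].cell_type
    elif labels - {cell_type, ""}:
        raise ValueError(
            f"samples labelled {sorted(labels)} do not match cell_type={cell_type!r}"
        )
    regions = list(samples[0].intervals)
    for s in samples[1:]:
        regions = intersect_bases(regions, s.intervals)
    return ConsensusSet(cell_type, tuple(regions), n_replicates=len(samples))


def classify_against(
    consensus: ConsensusSet,
    other_samples: Sequence[RegionSet],
    min_overlap: int = 1,
) -> list[RegionLabel]:
    """Label each consensus region DMR / CMR / PARTIAL against the samples of
    the other cell type, testing presence one sample at a time."""
    if not other_samples:
        raise ValueError("classify_against requires at least one other sample")
    cons_rs = consensus.as_region_set()
    support: dict[GenomicInterval, int] = {iv: 0 for iv in consensus.regions}
    for other in other_samples:
        for iv in overlap_filter(cons_rs, other, min_overlap):
            support[iv] += 1
    n_other = len(other_samples)
    labels: list[RegionLabel] = []
    for iv in consensus.regions:
        n = support[iv]
        label: Label = "DMR" if n == 0 else ("CMR" if n == n_other else "PARTIAL")
        labels.append(RegionLabel(iv, label, n))
    return labels


def _split(labels: Sequence[RegionLabel]) -> dict[Label, list[GenomicInterval]]:
    out: dict[Label, list[GenomicInterval]] = {"DMR": [], "CMR": [], "PARTIAL": []}
    for rl in labels:
        out[rl.label].append(rl.region)
    return out


def compare_cell_types(
    samples_a: Sequence[RegionSet],
    samples_b: Sequence[RegionSet],
    min_overlap: int = 1,
    directions: Literal["both", "a_only"] = "both",
) -> ComparisonResult:
    """Full two-cell-type comparison producing DMR/CMR/PARTIAL region sets.

    ``directions="both"`` (default) builds a consensus per cell type and
    classifies each against the other's replicates; ``"a_only"`` classifies
    only the A-side consensus (the single-reference variant), leaving DMR-B
    and PARTIAL-B empty.
    """
    if not samples_a or not samples_b:
        raise ValueError("need at least one sample per cell type")
    cons_a = build_consensus(samples_a)
    cons_b = build_consensus(samples_b)
    split_a = _split(classify_against(cons_a, samples_b, min_overlap))
    if directions == "both":
        split_b = _split(classify_against(cons_b, samples_a, min_overlap))
    elif directions == "a_only":
        split_b = {"DMR": [], "CMR": [], "PARTIAL": []}
    else:
        raise ValueError(f"unknown directions mode: {directions!r}")
    type_a, type_b = cons_a.cell_type, cons_b.cell_type

    def rs(name: str, cell_type: str, ivs: list[GenomicInterval]) -> RegionSet:
        return RegionSet(name, cell_type, tuple(ivs))

    return ComparisonResult(
        cell_type_a=type_a,
        cell_type_b=type_b,
        dmr_a=rs(f"dmr_{type_a}", type_a, split_a["DMR"]),
        dmr_b=rs(f"dmr_{type_b}", type_b, split_b["DMR"]),
        # shared regions surface from both directions; union counts them once
        cmr=rs("cmr", "common", merge(split_a["CMR"] + split_b["CMR"])),
        partial_a=rs(f"partial_{type_a}", type_a, split_a["PARTIAL"]),
        partial_b=rs(f"partial_{type_b}", type_b, split_b["PARTIAL"]),
    )


def summarize_comparison(
    n_dmr_a: int, n_dmr_b: int, n_total: int
) -> tuple[float, float, float]:
    """Percentages (DMR-A, DMR-B, CMR) of the combined region total.

    Values are returned unrounded; the report layer rounds half-up to the
    printed precision.  ``n_total`` counts DMR-A + DMR-B + CMR regions.
    """
    if n_total <= 0:
        raise ValueError("summary undefined for n_total = 0")
    if not (0 <= n_dmr_a + n_dmr_b <= n_total):
        raise ValueError("DMR counts must lie within [0, n_total]")
    pct_a = 100.0 * n_dmr_a / n_total
    pct_b = 100.0 * n_dmr_b / n_total
    return pct_a, pct_b, 100.0 * (n_total - n_dmr_a - n_dmr_b) / n_total
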