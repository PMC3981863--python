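"""Region-to-gene-feature annotation (promoter / exon / intron / intergenic).

Each region receives exactly one category by precedence
promoter > exon > intron > intergenic.  The promoter window is strand-aware:
TSS-``promoter_up`` .. TSS+``promoter_down`` where the TSS is ``tx_start``
for + genes and ``tx_end`` for - genes (upstream then extends to higher
coordinates).  When several genes could claim a region, the gene with the
largest base overlap in the winning feature type is reported; ties break
lexicographically by gene name.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .intervals import GenomicInterval, RegionSet

__all__ = [
    "Gene",
    "GeneModel",
    "RegionAnnotation",
    "read_refflat",
    "read_bed12",
    "annotate_regions",
]

Category = Literal["promoter", "exon", "intron", "intergenic"]
_PRECEDENCE: tuple[Category, ...] = ("promoter", "exon", "intron")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.name}: unknown strand symbol {self.strand!r}"
            )
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.name}: tx_start must be < tx_end")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.name}: exon [{s},{e}) outside tx span")

    def promoter_window(self, up: int, down: int) -> tuple[int, int]:
        """Strand-aware promoter interval, clipped at 0."""
        if self.strand == "+":
            lo, hi = self.tx_start - up, self.tx_start + down
        else:
            lo, hi = self.tx_end - down, self.tx_end + up
        return max(0, lo), max(0, hi)


@dataclass(frozen=True)
class GeneModel:
    genes: tuple[Gene, ...]

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass(frozen=True)
class RegionAnnotation:
    region: GenomicInterval
    category: Category
    gene: str


def read_refflat(path: str | Path) -> GeneModel:
    """Read a refFlat-style TSV: geneName, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated lists)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 fields")
            starts = [int(x) for x in f[5].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[6].rstrip(",").split(",") if x]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{lineno}: exonStarts/exonEnds mismatch")
            genes.append(
                Gene(f[0], f[1], f[2], int(f[3]), int(f[4]),
                     tuple(zip(starts, ends)))
            )
    return GeneModel(tuple(genes))


def read_bed12(path: str | Path) -> GeneModel:
    """Read a BED12 gene model (blocks become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(Gene(f[3], chrom, f[5], start, end, exons))
    return GeneModel(tuple(genes))


def _best_gene(candidates: list[tuple[int, str]]) -> str:
    # largest overlap wins; ties break lexicographically by name
    return min(candidates, key=lambda t: (-t[0], t[1]))[1]


def annotate_regions(
    regions: RegionSet | Sequence[GenomicInterval],
    model: GeneModel,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> tuple[list[RegionAnnotation], dict[str, int]]:
    """Assign one category per region plus a category count table.

    Returns ``(annotations, counts)`` where counts sums to the region count.
    """
    ivs = list(regions.intervals if isinstance(regions, RegionSet) else regions)
    genes_by_chrom = model.by_chrom()
    annotations: list[RegionAnnotation] = []
    for iv in ivs:
        overlaps: dict[Category, list[tuple[int, str]]] = {c: [] for c in _PRECEDENCE}
        for g in genes_by_chrom.get(iv.chrom, []):
            plo, phi = g.promoter_window(promoter_up, promoter_down)
            p_ov = max(0, min(iv.end, phi) - max(iv.start, plo))
            if p_ov > 0:
                overlaps["promoter"].append((p_ov, g.name))
            exon_ov = sum(
                max(0, min(iv.end, e) - max(iv.start, s)) for s, e in g.exons
            )
            if exon_ov > 0:
                overlaps["exon"].append((exon_ov, g.name))
            tx_ov = max(0, min(iv.end, g.tx_end) - max(iv.start, g.tx_start))
            intron_ov = tx_ov - exon_ov
            if intron_ov > 0:
                overlaps["intron"].append((intron_ov, g.name))
        for cat in _PRECEDENCE:
            if overlaps[cat]:
                annotations.append(
                    RegionAnnotation(iv, cat, _best_gene(overlaps[cat]))
                )
                break
        else:
            annotations.append(RegionAnnotation(iv, "intergenic", ""))
    counts = Counter(a.category for a in annotations)
    table = {c: counts.get(c, 0) for c in ("promoter", "exon", "intron", "intergenic")}
    return annotations, table


def write_annotation(
    annotations: Sequence[RegionAnnotation],
    counts: dict[str, int],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in annotations],
            "start": [a.region.start for a in annotations],
            "end": [a.region.end for a in annotations],
            "category": [a.category for a in annotations],
            "gene": [a.gene for a in annotations],
        }
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    with open(outdir / "category_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
        fh.write("\n")
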