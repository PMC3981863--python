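"""Seeded generators for every input the pipeline consumes.

Three generators, all pure functions of their configuration and seed:

* replicate methylated-region (peak) BED sets, built from a ground-truth
  catalog of shared and cell-type-specific regions with imperfect
  per-replicate detection, Gaussian boundary jitter and Poisson
  false-positive regions;
* expression intensity matrices with a planted set of up-/down-regulated
  probes over Gaussian noise, exported on the linear scale so the
  normalization stage is exercised;
* per-clone CpG methylation-percentage tables with configurable group means.

Truth regions are placed non-overlapping with a minimum gap, so DMR/CMR
truth labels stay unambiguous, and false positives are kept a full
``min_gap`` away from every truth region so they cannot blur the truth
bookkeeping of a downstream comparison.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, write_bed

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ExpressionTruth",
    "simulate_region_truth",
    "simulate_replicates",
    "simulate_expression",
    "simulate_methylation",
    "write_run",
]

RegionKind = Literal["shared", "specific_a", "specific_b"]


@dataclass(frozen=True)
class SimulationConfig:
    """Region-simulation parameters.

    Defaults describe a desk-scale MBD-seq-like experiment: three
    biological replicates per cell type, per-region detection probability
    0.7 (placing pairwise replicate concordance in the 50-80% band typical
    of enrichment peak sets), 50 bp boundary jitter (the scale set by
    100-300 bp sonication fragments) and a light false-positive load.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_shared: int = 200
    n_specific_a: int = 50
    n_specific_b: int = 30
    region_length_range: tuple[int, int] = (500, 2000)
    min_gap: int = 1000
    n_replicates_a: int = 3
    n_replicates_b: int = 3
    p_detect: float = 0.7
    boundary_jitter_sd: float = 50.0
    fp_rate: float = 20.0
    cell_type_a: str = "iPS_WT"
    cell_type_b: str = "iPS_KO"

    def validate(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("p_detect must lie in [0, 1]")
        lo, hi = self.region_length_range
        if not 0 < lo <= hi:
            raise ValueError("region_length_range must satisfy 0 < min <= max")
        if self.min_gap < 0 or self.boundary_jitter_sd < 0 or self.fp_rate < 0:
            raise ValueError("min_gap, boundary_jitter_sd and fp_rate must be >= 0")
        if min(self.n_shared, self.n_specific_a, self.n_specific_b) < 0:
            raise ValueError("region counts must be >= 0")
        if self.n_replicates_a < 1 or self.n_replicates_b < 1:
            raise ValueError("need >=1 replicate per cell type")
        if not self.chrom_lengths or min(self.chrom_lengths.values()) <= 0:
            raise ValueError("chrom_lengths must map chromosomes to positive bp")


@dataclass(frozen=True)
class TruthRegion:
    region: GenomicInterval
    kind: RegionKind


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth region catalog against which recovery is scored."""

    regions: tuple[TruthRegion, ...]

    def of_kind(self, kind: RegionKind) -> list[GenomicInterval]:
        return [t.region for t in self.regions if t.kind == kind]

    @property
    def shared(self) -> list[GenomicInterval]:
        return self.of_kind("shared")

    @property
    def specific_a(self) -> list[GenomicInterval]:
        return self.of_kind("specific_a")

    @property
    def specific_b(self) -> list[GenomicInterval]:
        return self.of_kind("specific_b")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [t.region.chrom for t in self.regions],
                "start": [t.region.start for t in self.regions],
                "end": [t.region.end for t in self.regions],
                "kind": [t.kind for t in self.regions],
            }
        )


class GenomeCapacityError(RuntimeError):
    """The genome cannot hold the requested regions at the required gap."""


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


class _GapPlacer:
    """Rejection-samples intervals keeping >= gap bp to everything placed."""

    def __init__(self, chrom_lengths: dict[str, int], gap: int,
                 rng: np.random.Generator) -> None:
        self.gap = gap
        self.rng = rng
        self.chroms = sorted(chrom_lengths)
        self.lengths = np.array([chrom_lengths[c] for c in self.chroms], float)
        self.weights = self.lengths / self.lengths.sum()
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}

    def _fits(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.placed[chrom]
        k = bisect_left(ivs, (start, end))
        if k > 0 and ivs[k - 1][1] + self.gap > start:
            return False
        if k < len(ivs) and end + self.gap > ivs[k][0]:
            return False
        return True

    def block(self, intervals: Sequence[GenomicInterval]) -> None:
        for iv in intervals:
            insort(self.placed[iv.chrom], (iv.start, iv.end))

    def place(self, length_range: tuple[int, int], max_tries: int) -> GenomicInterval:
        lo, hi = length_range
        for _ in range(max_tries):
            ci = self.rng.choice(len(self.chroms), p=self.weights)
            chrom = self.chroms[ci]
            length = int(self.rng.integers(lo, hi + 1))
            span = int(self.lengths[ci]) - length
            if span < 0:
                continue
            start = int(self.rng.integers(0, span + 1))
            if self._fits(chrom, start, start + length):
                insort(self.placed[chrom], (start, start + length))
                return GenomicInterval(chrom, start, start + length)
        raise GenomeCapacityError(
            f"could not place an interval of {lo}-{hi} bp with gap "
            f">= {self.gap} after {max_tries} tries; genome too crowded"
        )


def simulate_region_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the non-overlapping ground-truth region catalog.

    Deterministic for a fixed config/seed; regions are pairwise separated by
    >= ``min_gap`` bp and labels are assigned uniformly at random over the
    placed positions.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    n_total = config.n_shared + config.n_specific_a + config.n_specific_b
    placer = _GapPlacer(config.chrom_lengths, config.min_gap, rng)
    regions = [
        placer.place(config.region_length_range, max_tries=1000)
        for _ in range(n_total)
    ]
    kinds: list[RegionKind] = (
        ["shared"] * config.n_shared
        + ["specific_a"] * config.n_specific_a
        + ["specific_b"] * config.n_specific_b
    )
    rng.shuffle(kinds)  # decouple label from placement order
    truth = tuple(
        TruthRegion(region, kind) for region, kind in zip(sorted(regions), kinds)
    )
    return SimulationTruth(truth)


def _jitter_interval(
    iv: GenomicInterval, sd: float, rng: np.random.Generator
) -> GenomicInterval:
    if sd == 0:
        return iv
    j1, j2 = np.round(rng.normal(0.0, sd, size=2)).astype(int)
    start = max(0, iv.start + int(j1))
    end = iv.end + int(j2)
    if end <= start:  # truncate so the interval stays non-empty
        end = start + 1
    return GenomicInterval(iv.chrom, start, end)


def simulate_replicates(
    truth: SimulationTruth, config: SimulationConfig
) -> tuple[list[RegionSet], list[RegionSet]]:
    """Generate per-replicate RegionSets for both cell types.

    Each replicate of type A contains every shared / A-specific truth region
    independently with probability ``p_detect``, with endpoints jittered by
    rounded Gaussian noise, plus Poisson(``fp_rate``) false-positive regions
    placed uniformly at least ``min_gap`` away from all truth regions
    (symmetric for B).
    """
    config.validate()
    rng = _rng(config.seed, 1)
    all_truth = [t.region for t in truth.regions]
    eligible = {
        config.cell_type_a: truth.shared + truth.specific_a,
        config.cell_type_b: truth.shared + truth.specific_b,
    }
    out: dict[str, list[RegionSet]] = {config.cell_type_a: [], config.cell_type_b: []}
    for cell_type, n_reps in (
        (config.cell_type_a, config.n_replicates_a),
        (config.cell_type_b, config.n_replicates_b),
    ):
        pool = sorted(eligible[cell_type])
        for rep in range(n_reps):
            detected = [
                _jitter_interval(iv, config.boundary_jitter_sd, rng)
                for iv in pool
                if rng.random() < config.p_detect
            ]
            n_fp = int(rng.poisson(config.fp_rate))
            if n_fp:
                placer = _GapPlacer(config.chrom_lengths, config.min_gap, rng)
                placer.block(all_truth)
                detected.extend(
                    placer.place(config.region_length_range, max_tries=1000)
                    for _ in range(n_fp)
                )
            out[cell_type].append(
                RegionSet(f"{cell_type}_rep{rep + 1}", cell_type, tuple(detected))
            )
    return out[config.cell_type_a], out[config.cell_type_b]


@dataclass(frozen=True)
class ExpressionTruth:
    up_probes: tuple[str, ...]
    down_probes: tuple[str, ...]
    log2fc: float


def simulate_expression(
    n_probes: int = 5000,
    n_up: int = 26,
    n_down: int = 12,
    log2fc: float = 3.0,
    noise_sd: float = 0.25,
    n_per_group: int = 6,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, str], ExpressionTruth]:
    """Linear-scale intensity matrix with planted differential probes.

    Baseline log2 intensities are drawn once per probe; planted probes get a
    +/-``log2fc`` group-A offset; i.i.d. Gaussian noise (``noise_sd``) is
    added per cell; the matrix is exported as 2^x so the caller's
    normalization step operates on linear intensities.  Returns
    ``(matrix, sample->group map, truth)``; "up" probes are higher in
    group A.
    """
    if n_up < 0 or n_down < 0 or n_up + n_down > n_probes:
        raise ValueError("need 0 <= n_up + n_down <= n_probes")
    if n_per_group < 2:
        raise ValueError("need >=2 samples per group")
    rng = _rng(seed, 2)
    probes = [f"probe_{i:05d}" for i in range(n_probes)]
    samples_a = [f"A{i + 1}" for i in range(n_per_group)]
    samples_b = [f"B{i + 1}" for i in range(n_per_group)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    planted = rng.choice(n_probes, size=n_up + n_down, replace=False)
    effect = np.zeros(n_probes)
    effect[planted[:n_up]] = log2fc
    effect[planted[n_up:]] = -log2fc
    log2 = np.tile(baseline[:, None], 2 * n_per_group).astype(float)
    log2[:, :n_per_group] += effect[:, None]
    log2 += rng.normal(0.0, noise_sd, size=log2.shape)
    matrix = pd.DataFrame(
        np.power(2.0, log2), index=pd.Index(probes, name="probe"),
        columns=samples_a + samples_b,
    )
    groups = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    truth = ExpressionTruth(
        up_probes=tuple(probes[i] for i in sorted(planted[:n_up])),
        down_probes=tuple(probes[i] for i in sorted(planted[n_up:])),
        log2fc=log2fc,
    )
    return matrix, groups, truth


def simulate_methylation(
    group_means: dict[str, float],
    n_clones: int = 3,
    n_cpgs: int = 4,
    sd: float = 5.0,
    locus: str = "locus1",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-clone CpG methylation-percentage table.

    Values are Gaussian around each group's mean, clipped to [0, 100];
    deterministic per seed.
    """
    for g, m in group_means.items():
        if not 0.0 <= m <= 100.0:
            raise ValueError(f"group {g!r}: mean {m} outside [0, 100]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _rng(seed, 3)
    rows = []
    for group in sorted(group_means):
        for clone in range(n_clones):
            vals = np.clip(
                rng.normal(group_means[group], sd, size=n_cpgs), 0.0, 100.0
            )
            for cpg, v in enumerate(vals):
                rows.append(
                    {
                        "clone_id": f"{group}_clone{clone + 1}",
                        "group": group,
                        "locus": locus,
                        "cpg_index": cpg,
                        "methylation_pct": float(v),
                    }
                )
    return pd.DataFrame(rows)


def write_run(outdir: str | Path, config: SimulationConfig) -> Path:
    """Simulate a full input bundle under ``outdir``.

    Writes per-replicate BED files, a sample sheet (sample_id, cell_type,
    path), the truth catalog, an expression matrix + group sheet + truth,
    a methylation table, and the config echoed as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_region_truth(config)
    samples_a, samples_b = simulate_replicates(truth, config)

    sheet_rows = []
    for rs in samples_a + samples_b:
        bed = outdir / f"{rs.sample_id}.bed"
        write_bed(rs, bed)
        sheet_rows.append(
            {"sample_id": rs.sample_id, "cell_type": rs.cell_type, "path": bed.name}
        )
    pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(outdir / "region_truth.tsv", sep="\t", index=False)

    matrix, groups, expr_truth = simulate_expression(seed=config.seed)
    matrix.to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(outdir / "expression_groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "probe": expr_truth.up_probes + expr_truth.down_probes,
            "direction": ["up"] * len(expr_truth.up_probes)
            + ["down"] * len(expr_truth.down_probes),
            "log2fc": expr_truth.log2fc,
        }
    ).to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)

    meth = simulate_methylation(
        {config.cell_type_a: 80.0, config.cell_type_b: 20.0}, seed=config.seed
    )
    meth.to_csv(outdir / "methylation.tsv", sep="\t", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
        fh.write("\n")
    return outdir
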