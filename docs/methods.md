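# Methods

## Scope and data model

`dmrpipe` operates downstream of read alignment and peak calling: its input
unit is a per-sample set of already-called methylated regions (BED
intervals), one file per biological replicate, grouped by cell type.
Coordinates are 0-based half-open throughout (the BED convention; sources
that leave the convention unstated are read as BED). Each sample's
intervals are sorted and merged at construction, so "number of regions" is
unambiguous regardless of how the upstream peak caller handled adjacency.
Chromosome names are compared as exact strings — no "chr" aliasing — to
keep every overlap decision deterministic and documentable.

## Consensus and DMR/CMR classification

The per-cell-type consensus is the base-pair intersection of all
replicates. We chose intersection over the alternative reading ("regions of
replicate 1 that are present in all others") because it is order-independent
and symmetric in the replicates; the single-reference variant remains
available as `directions="a_only"` in `compare_cell_types` (CLI flag
`--one-directional`).

Presence of a consensus region in an other-type sample means ≥ `min_overlap`
bp shared with at least one of that sample's regions; `min_overlap` defaults
to 1 bp and is exposed because no principled overlap fraction exists for
presence/absence peak data. Classification is purely presence-based: a
region methylated in all samples of both types is a CMR even if its
enrichment magnitude differs.

Bookkeeping choices that affect the reported numbers:

* **PARTIAL regions** (supported by some but not all other-type replicates)
  are excluded from the reported total and percentages. With this
  convention the three percentages (DMR-A, DMR-B, CMR) always sum to 100,
  which matches how such pie-chart summaries are conventionally printed.
* **CMR unification**: the A-direction and B-direction CMR lists describe
  the same biology, so they are merged by coordinate union and counted
  once.
* **Rounding**: percentages are computed unrounded and rounded half-up to
  one decimal only at the report layer.

All three interval primitives (merge, base intersection, presence filter)
and the full comparison are validated against an independent per-base
bitmap implementation on toy genomes, and the intersection/presence
semantics are additionally cross-checked against the reference
`bedtools intersect` / `intersect -u` behavior.

## Replicate concordance

For samples $a, b$: proportion
$= (n_a^{ov} + n_b^{ov}) / (n_a + n_b)$, where $n_x^{ov}$ counts regions of
$x$ overlapping ≥ 1 region of the other sample (each region counted once,
however many partners it overlaps). The two-sided numerator is chosen so
identical samples score exactly 1.0 — a one-sided numerator over the
two-sample denominator would cap at 0.5, which no concordance measure
should. The proportion is undefined (an error, not 0) when both samples are
empty.

## Annotation

Each region gets exactly one category with precedence
promoter > exon > intron > intergenic. The promoter window is
TSS−2000..TSS+500 bp, strand-aware (TSS = `tx_start` on +, `tx_end` on −);
both extents are parameters since no universal convention exists. Among
genes offering the winning category, the largest base overlap wins, ties
broken lexicographically by gene name. Gene models are read from
refFlat-style TSV or BED12.

## Expression screen

"75th-percentile" normalization is implemented as a percentile **shift** in
log2 space: each sample's log2 values are offset so its 75th percentile
equals the across-sample median of 75th percentiles. This is the standard
single-channel microarray preset (a per-sample location shift); full
quantile normalization is deliberately not used, as it is not parameterized
by a single percentile and would destroy within-sample rank structure
beyond what a location shift implies. The shift is idempotent.

The per-probe test is a Student's two-sample t-test with pooled variance
(Welch available via `equal_var=False`). Degenerate probes with zero
variance in both groups get p = 1 when the means are equal and p = 0
otherwise — an explicit edge rule rather than a NaN. BH adjustment follows
the step-up definition $q_{(i)} = \min_{j \ge i} (m/j)\,p_{(j)}$, capped at
1; it is verified against a brute-force evaluation of that definition and
against `statsmodels`' implementation. A probe is called up/down only when
both the fold-change gate (|log2FC| > log2 2) and the q-value gate
(q < 0.05) pass; "up" means higher in the first group, and the orientation
is an explicit argument because it is a labeling convention, not a property
of the data.

Sample clustering uses average linkage on 1 − Pearson correlation between
sample profiles (zero-variance profiles are rejected by name). qPCR-style
relative expression is ΔΔCt: per-sample $2^{-(Ct_{target}-Ct_{ref})}$,
scaled so the calibrator group's mean is exactly 1.

## Methylation summaries

The clone is the statistical unit: per-CpG percentages are first averaged
within a clone at a locus, then clone means are summarized per group (mean,
sample SD with n−1) and compared with a pooled-variance t-test. A
single-clone group reports SD 0 with n = 1 as a flag. Global repeat assays
(B1/LINE-1 style) are ordinary loci with many CpG rows — no special
handling.

## Synthetic data

The generators emulate the *structure* of enrichment peak data, not its
read-level physics:

* **Truth catalog**: `n_shared` + `n_specific_a` + `n_specific_b`
  non-overlapping regions (500–2000 bp, the scale of enrichment peaks),
  placed by rejection sampling with ≥ `min_gap` (default 1000 bp) between
  any two, labels assigned uniformly at random over placements.
  Non-overlapping truth keeps DMR/CMR truth labels unambiguous.
* **Replicates**: each eligible truth region enters a replicate
  independently with probability `p_detect` (default 0.7, which puts
  pairwise replicate concordance in the 50–80% band typical of real
  enrichment peak sets, since the expected concordance is ≈ `p_detect`);
  endpoints are jittered by rounded Gaussian noise (default sd 50 bp,
  anchored to the 100–300 bp sonication-fragment scale), truncated so the
  interval stays non-empty. Poisson(`fp_rate`) false positives per
  replicate are placed uniformly at least `min_gap` away from all truth
  regions — a documented simplification so a false positive can never
  silently convert a DMR to PARTIAL in the truth bookkeeping.
* **Expression**: per-probe baseline log2 intensities ~ N(8, 2); planted
  probes (defaults 26 up / 12 down of 5000, |log2FC| = 3, noise sd 0.25,
  6 samples per group) receive the group offset; the matrix is exported as
  2^x so the normalization stage is exercised on linear intensities.
* **Methylation**: per-CpG values are Gaussian around the group mean,
  clipped to [0, 100].

All generators are pure functions of (config, seed) and byte-identical on
repeat; emitted BED files round-trip through the BED reader.

What passing tests show — and what they do not: the simulators produce
independent per-region detection and independent Gaussian probe noise, so
recovery results certify the *logic* of the pipeline (set algebra,
classification, thresholds, multiplicity correction), not its behavior
under correlated noise, CpG-density-dependent enrichment efficiency,
copy-number artifacts, or probe cross-hybridization, none of which are
modeled.

## Calibration expectations used in tests

With detection probability $p$ and $k$ replicates per side and no
jitter/false positives, a shared truth region is recovered as CMR iff
detected in all $2k$ replicates, so the CMR count is Binomial($n_{shared}$,
$p^{2k}$); the suite checks the mean over 100 seeds against this expectation
at three standard errors. The null expression screen (no planted probes)
must keep the mean significant fraction at q < 0.05 below 5%.

## Problem sizes and numerical choices

Simulated checks use desk-scale sizes — toy genomes ≤ 10 kb for
bitmap-oracle equivalence (500 randomized cases), 280–380 truth regions on
a 10 Mb two-chromosome genome for recovery, 5000 probes for the screen —
chosen so the full suite and the acceptance script each run in seconds
while keeping every statistical check well-powered. Percentile computation
uses linear interpolation (numpy default); normalization equality is
asserted to 1e−9; BH equivalence to 1e−12. The published region counts of
the three real comparisons are treated as inputs to the summary layer; one
printed figure (1,934 of 43,458 shown as 4.4%) disagrees with its own
arithmetic (4.4503% → 4.5 at one decimal), and the package reports the
computed value.
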