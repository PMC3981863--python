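"""Independent brute-force oracles used across the test suite.

Interval operations are checked against per-base boolean bitmaps on toy
genomes (<= 10 kb per chromosome), the BH adjustment against a literal
evaluation of the step-up definition, and average-linkage clustering
against an exhaustive pairwise-distance agglomeration.  These functions
deliberately share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

from dmrpipe.intervals import GenomicInterval

TOY_GENOME = {"chrA": 10_000, "chrB": 8_000}


def bitmap(intervals, genome=None):
    genome = genome or TOY_GENOME
    bm = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in intervals:
        bm[iv.chrom][iv.start : iv.end] = True
    return bm


def intervals_from_bitmap(bm):
    out = []
    for chrom in sorted(bm):
        mask = bm[chrom].astype(int)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def bitmap_and(ivs_a, ivs_b, genome=None):
    genome = genome or TOY_GENOME
    ba, bb = bitmap(ivs_a, genome), bitmap(ivs_b, genome)
    return intervals_from_bitmap({c: ba[c] & bb[c] for c in ba})


def brute_force_overlap_keep(query_ivs, subject_ivs, min_overlap=1):
    """All-pairs O(n*m) presence filter."""
    kept = []
    for q in query_ivs:
        for s in subject_ivs:
            if q.overlap_length(s) >= min_overlap:
                kept.append(q)
                break
    return kept


def random_intervals(rng, n, genome=None, max_len=500):
    genome = genome or TOY_GENOME
    chroms = sorted(genome)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[chrom] - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m/j * p_(j))."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m / (j + 1) * p[order[j]] for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_force_average_linkage(dist):
    """Exhaustive agglomeration on a condensed-free square distance matrix.

    Returns a list of (member_set_a, member_set_b, height) merges using
    unweighted average linkage (UPGMA), lowest-index tie-breaking.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i_pos, ki in enumerate(keys):
            for kj in keys[i_pos + 1 :]:
                d = np.mean(
                    [dist[a, b] for a in clusters[ki] for b in clusters[kj]]
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, ki, kj)
        d, ki, kj = best
        merges.append((clusters[ki], clusters[kj], d))
        clusters[min(ki, kj)] = clusters[ki] | clusters[kj]
        del clusters[max(ki, kj)]
    return merges


def bitmap_compare_cell_types(reps_a, reps_b, genome=None):
    """Full DMR/CMR comparison evaluated purely on per-base bitmaps.

    Consensus per type = AND of replicate bitmaps; each consensus run is a
    region; presence in an other-type sample = any shared base with that
    sample's bitmap.  Returns dict of interval lists keyed by category.
    """
    genome = genome or TOY_GENOME
    bms_a = [bitmap(r.intervals, genome) for r in reps_a]
    bms_b = [bitmap(r.intervals, genome) for r in reps_b]

    def consensus(bms):
        out = {c: np.ones(n, dtype=bool) for c, n in genome.items()}
        for bm in bms:
            for c in out:
                out[c] &= bm[c]
        return out

    def classify(cons_bm, other_bms):
        regions = intervals_from_bitmap(cons_bm)
        dmr, cmr, partial = [], [], []
        for iv in regions:
            n_sup = sum(
                bool(bm[iv.chrom][iv.start : iv.end].any()) for bm in other_bms
            )
            if n_sup == 0:
                dmr.append(iv)
            elif n_sup == len(other_bms):
                cmr.append(iv)
            else:
                partial.append(iv)
        return dmr, cmr, partial

    dmr_a, cmr_a, partial_a = classify(consensus(bms_a), bms_b)
    dmr_b, cmr_b, partial_b = classify(consensus(bms_b), bms_a)
    cmr_bm = bitmap(cmr_a + cmr_b, genome)
    return {
        "dmr_a": dmr_a,
        "dmr_b": dmr_b,
        "cmr": intervals_from_bitmap(cmr_bm),
        "partial_a": partial_a,
        "partial_b": partial_b,
    }
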