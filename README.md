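# dmrpipe

Comparative DNA-methylation analysis for enrichment-based sequencing
(MBD-seq / MeDIP-seq style) peak sets, built around replicate-consensus
region calling. Given per-replicate methylated-region BED files for two
cell types, `dmrpipe` answers the question a reprogramming or epigenomics
study asks of such data: *which regions are methylated in one cell type but
not the other (DMRs), which are methylated in both (CMRs), and how
concordant are the biological replicates?* It also ships the surrounding
analyses such a study pairs with the methylation comparison — a two-group
microarray expression screen, gene-feature annotation of regions,
pyrosequencing-style methylation summaries — and seeded synthetic-data
generators for every input, so the whole pipeline is testable without any
sequencing data.

## The method

For each cell type with replicates $r_1,\dots,r_k$ (each a set of genomic
intervals), the **consensus set** is the base-pair intersection
$C = r_1 \cap r_2 \cap \cdots \cap r_k$, so every consensus base is
supported by every replicate. Each consensus region of cell type A is then
tested for presence (≥ 1 bp overlap by default) in each replicate of cell
type B, one sample at a time:

* detected in **no** B replicate → **DMR** of A (differentially methylated);
* detected in **all** B replicates → **CMR** (commonly methylated);
* detected in some but not all → **PARTIAL** (kept, but excluded from the
  summary percentages).

The classification is run in both directions and the two CMR lists are
unified by coordinate union so shared regions count once. The summary
percentages are $100\,n_{\mathrm{DMR-A}}/N$, $100\,n_{\mathrm{DMR-B}}/N$ and
$100\,n_{\mathrm{CMR}}/N$ with $N = n_{\mathrm{DMR-A}} + n_{\mathrm{DMR-B}}
+ n_{\mathrm{CMR}}$.

Replicate **concordance** between two samples is the number of regions of
either sample overlapping the other, divided by the total regions in the
two samples — 1.0 for identical peak sets, 0.0 for disjoint ones.

The **expression screen** log2-transforms intensities, aligns each sample's
75th percentile to the cross-sample median (percentile-shift
normalization), runs a pooled-variance two-sample t-test per probe, applies
Benjamini–Hochberg correction, and calls a probe up/down when
$|\log_2 FC| > \log_2 2$ and $q < 0.05$.

## Worked example

```python
from dmrpipe import (SimulationConfig, simulate_region_truth,
                     simulate_replicates, compare_cell_types)

cfg = SimulationConfig(seed=1, n_shared=200, n_specific_a=50, n_specific_b=30,
                       p_detect=1.0, boundary_jitter_sd=0.0, fp_rate=0.0)
truth = simulate_region_truth(cfg)
reps_wt, reps_ko = simulate_replicates(truth, cfg)
result = compare_cell_types(reps_wt, reps_ko)
print(result.summary_dict())
```

prints

```
{'cell_type_a': 'iPS_WT', 'cell_type_b': 'iPS_KO', 'n_dmr_a': 50,
 'n_dmr_b': 30, 'n_cmr': 200, 'n_partial_a': 0, 'n_partial_b': 0,
 'n_total': 280, 'pct_dmr_a': 17.9, 'pct_dmr_b': 10.7, 'pct_cmr': 71.4}
```

With perfect detection and no noise the comparison recovers the planted
truth exactly: the 50 regions methylated only in `iPS_WT` come back as its
DMRs, the 30 `iPS_KO`-specific regions as the other side's DMRs, and the
200 shared regions as CMRs (71.4% of the 280 reported regions).

The same pipeline is available from the shell:

```sh
dmrpipe simulate --out run --seed 1
dmrpipe compare --sample-sheet run/sample_sheet.tsv --out run/cmp
dmrpipe report --run-dir run/cmp
```

plus `concordance`, `annotate`, `de` and `methyl` subcommands; every run
directory carries a `provenance.json` with the parameters used.

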