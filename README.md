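# mirsieve

Small RNA deep sequencing produces millions of short reads whose collapsed
unique-tag counts span six orders of magnitude, and the bulk of distinct
tags are low-count noise that is poorly reproducible between biological
replicates. `mirsieve` implements a complete miRNA quantification workflow
for this situation — aimed at anyone profiling cellular or secreted
(exosomal) miRNAs with replicated libraries:

1. **Collapse** — adapter trimming (longest exact suffix–prefix overlap),
   insert-length filtering (default 18–35 nt), and collapsing of identical
   reads into a unique-tag count table.
2. **Map** — ungapped alignment of every tag against a mature-miRNA
   reference at every offset with a bounded Hamming distance (default 3
   mismatches); uniquely-best tags are annotated, and annotated counts are
   projected onto genomic loci as browser-loadable peak tracks (BED5 and
   variableStep wiggle).
3. **Threshold** — the core statistic: an adaptive noise threshold from an
   iterative two-sample Kolmogorov–Smirnov sweep. For each integer cutoff
   *t*, the KS distance
   D(t) = sup_x |F₁(x; counts ≥ t) − F₂(x; counts ≥ t)|
   between the two replicates' retained count distributions is computed;
   D(t) falls while discordant noise is stripped away and flattens once only
   the shared signal remains. The selected threshold is the smallest *t* at
   which D first reaches its minimum (at a 2.5 %-of-range resolution).
4. **Tier and agree** — counts are banded into Low (< 32), Mid (32–10,000)
   and High (> 10,000) abundance tiers; replicate agreement of tier
   membership is quantified with Cohen's kappa,
   κ = (p_o − p_e) / (1 − p_e), over a configurable tag universe.
5. **Rank and compare** — per-sample abundance ranking above the threshold,
   top-N set comparisons across replicates, platforms or compartments, and
   miRNA-family summaries (e.g. the let-7 family).
6. **Sieve networks** — two gene-interaction networks (alignment-derived
   vs prediction-derived targets) are intersected for common nodes, ranked
   by min-degree across both; for candidate genes, group-wise expression
   ratios are computed after within-sample normalization by a housekeeping
   gene (GAPDH by default).

A first-class synthetic-data module generates count tables with the
two-component structure described above (replicate-discordant exponential
noise below a boundary, shared log-normal signal at or above it), FASTQ
reads, hub-sharing network pairs and expression matrices with known fold
changes, so every stage is testable without downloads.

## Worked example

```python
from mirsieve import (datasets, rank_mirnas, assign_tiers, top_n_overlap,
                      family_summary, MixtureSpec, simulate_count_replicates,
                      count_distribution, adaptive_threshold)

ic = datasets.load_intracellular_top()      # bundled example: 16 tags, 2 replicates
ec = datasets.load_extracellular_top()      # bundled example: 20 tags, 3 replicates

ranked = rank_mirnas(ic, "IC2", min_count=32)
print("top intracellular (IC2):", ranked.entries[0])
members, total = family_summary(ranked, "hsa-let-7")
print("let-7 family members in top list:", members, "summed reads:", total)

partition = assign_tiers(ic)
print("IC1 tiers:", sorted(set(partition.tiers["IC1"].values())))

universe = set(rank_mirnas(ic, "IC1", 32).names) | set(rank_mirnas(ec, "EC1", 32).names)
cmp = top_n_overlap(rank_mirnas(ic, "IC1", 32), rank_mirnas(ec, "EC1", 32), 20, universe)
print(f"intra vs extra top-name overlap: {cmp.intersection_size} (kappa {cmp.kappa:.2f})")

table = simulate_count_replicates(MixtureSpec(seed=1))
res = adaptive_threshold(count_distribution(table, "rep1"),
                         count_distribution(table, "rep2"))
print("KS-selected threshold (simulated replicates, boundary 32):",
      res.selected_threshold)
```

prints

```
top intracellular (IC2): ('hsa-let-7f', 1076532)
let-7 family members in top list: 6 summed reads: 1976501
IC1 tiers: ['High']
intra vs extra top-name overlap: 14 (kappa -0.16)
KS-selected threshold (simulated replicates, boundary 32): 32
```

hsa-let-7f dominates the cellular compartment at 1,076,532 reads; all 16
bundled intracellular tags sit in the High tier; 14 of the 16 intracellular
names recur among the 20 extracellular names (the kappa is negative because
the 22-name universe is nearly saturated, so this much overlap is below
chance agreement); and on a simulated replicate pair whose noise/signal
boundary is 32, the KS sweep recovers exactly 32.

## Command line

A `mirsieve` console script exposes each stage (`collapse`, `map`, `sweep`,
`tiers`, `rank`, `networks`, `simulate`) and a `run-all` subcommand driven
by a single YAML config; see `mirsieve --help`. Exit codes: 0 success,
2 configuration error, 3 data error.

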