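# panchrom3d

A toolkit for **pan-3D genome analysis**: asking how chromatin architecture —
A/B compartments, TAD boundaries, chromatin loops and long-range
cis-regulatory elements (LT-CREs) — and structural variation are conserved or
reorganized across many genome assemblies of one species, and how structural
variants (SVs) under selection intersect that architecture. It is aimed at
comparative and regulatory genomicists who have per-genome feature calls
(boundaries, loops, ATAC peaks, SVs, genotypes) and want the cross-genome
statistics, not the upstream read processing.

## What it computes

**Conservation classification.** Features from N genomes are lifted onto a
backbone coordinate system through block liftover maps and clustered
(interval features merged with a kind-specific gap — 40 kb for TAD
boundaries, 500 bp for LT-CREs; loops linked when both anchor pairs overlap
reciprocally by > 50% of the shorter anchor; SVs merged when same-type
breakpoints lie within 1 kb). Each cluster present in *c* of *n* genomes is

- **core** if c = n, **softcore** if c < n and c/n ≥ 0.9,
- **private** if c = 1, **dispensable** otherwise,

and pan/core accumulation curves are computed over random genome orders.

**Chromatin architecture.** From a binned contact matrix *M*, the insulation
score of bin *b* is the diamond mean
IS(b) = mean{ M[i,j] : b−w ≤ i < b < j ≤ b+w }, normalized as
log₂(IS/⟨IS⟩). Boundaries are local minima whose topographic prominence
passes Li's minimum cross-entropy threshold; TADs are inter-boundary spans.
Compartments come from the sign of the first eigenvector of the
observed/expected Pearson correlation matrix, oriented by gene density.
Loops are typed E-E / E-G / G-G from anchor content (E = LT-CRE anchor,
G = 2-kb-upstream-of-TSS anchor).

**SV analysis.** SURVIVOR-style merging, junction-signature mechanism calls
(TEI, NHEJ, VNTR, FoSTeS/MMBIR, NAHR, alt-EJ), 100-kb breakpoint hotspots,
SV-gene pairing within 5 kb of breakpoints, and genotype QC (calls kept only
if DP > 2 and GQ > 10; sites dropped at > 50% missingness or MAF < 0.05).

**Selection and enrichment.** Weir–Cockerham (1984) Fst
θ̂ = a/(a+b+c) from the among-population / among-individual / within-individual
variance components; per-site π = 2p(1−p)·n/(n−1) with 50-kb/25-kb sliding
windows; candidate SVs = joint top-5% of Fst and Pi-ratio, ranked by
Euclidean distance on scaled axes; a length-preserving bootstrap null (1,000
region relocations) for SV coverage of chromatin features; SV-loop gene
linkage through loop anchors.

**Capture Hi-C.** Interactions with a confidence score ≥ 3 are
high-confidence; an MT-specific interaction satisfies MT ≥ 3, WT < 3 and
MT − WT > 3 (and vice versa).

A fully deterministic synthetic-data module plants every one of these
signals with known truth, so the whole pipeline is testable without any
external data.

## Worked example

```python
import numpy as np
from panchrom3d import SimConfig, simulate_pan_dataset
from panchrom3d.pan import lift_features, cluster_lifted_intervals, category_counts
from panchrom3d.synth import plant_tads, simulate_contact_matrix
from panchrom3d.chromatin import insulation_score, call_boundaries, \
    passing_boundaries, call_tads

cfg = SimConfig(seed=1, chrom_sizes={"chr1": 30_000_000},
                n_boundaries=30, n_loops=30, n_ltcres=50, n_svs=100,
                n_gene_families=200)
ds = simulate_pan_dataset(cfg)

lifted, unmapped = lift_features(ds.boundaries, ds.maps)
clusters = cluster_lifted_intervals(lifted, max_gap=40_000)
print("boundary clusters:", len(clusters))
print("category counts:", category_counts(clusters))
recovered = [c.category for c in clusters]
print("agreement with planted classes:",
      np.mean([r == t for r, t in zip(recovered, ds.truth.classes["boundary"])]))

tads = plant_tads("chr1", n_tads=20, bin_size=40_000, seed=1)
cm = simulate_contact_matrix(tads, 40_000, within=5, between=1, seed=1)
calls = passing_boundaries(call_boundaries(insulation_score(cm, w=2)))
print("called boundaries:", len(calls), "planted junctions:", len(tads) - 1)
print("TAD spans:", len(call_tads(calls, cm.chrom, cm.n_bins * cm.bin_size)))
```

prints

```
boundary clusters: 30
category counts: {'core': 10, 'softcore': 4, 'dispensable': 9, 'private': 7}
agreement with planted classes: 1.0
called boundaries: 20 planted junctions: 19
TAD spans: 21
```

Thirty planted boundary clusters are recovered with their exact conservation
classes (the generator draws classes first, then membership, so exact
recovery is the correctness contract). On the Poisson contact matrix, 19 of
the 20 calls sit at planted TAD junctions; the one extra call is a noise
minimum that cleared the Li threshold — typical of the ~0.98 precision this
setting achieves on average.

There is also a CLI:

```bash
panchrom3d simulate --seed 1 --outdir sim_out
panchrom3d pan-classify --kind boundary --inputs sim_out --max-gap 40000
panchrom3d enrich --features svs.bed --regions boundaries.bed \
    --chrom-sizes sizes.tsv -N 1000 --seed 1
```

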