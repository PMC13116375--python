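# Methods

This note records the models, conventions and design choices behind
panchrom3d, in the spirit of the methods documentation of statsmodels or
msprime: enough detail to know exactly what is computed, which knobs matter,
and what the synthetic benchmarks do and do not demonstrate.

## Coordinates, overlap and liftover

All intervals are 0-based half-open (`[start, end)`), the BED convention;
GFF-lite gene records are converted from 1-based inclusive on read. Strand
is carried as metadata but ignored by all overlap operations except the
"2 kb upstream of the TSS" window, which is strand-aware (configurable).

*Reciprocal overlap* between two intervals is the shared length divided by
the length of the **shorter** interval, and the loop-conservation rule
requires strictly more than 0.5 on both anchor pairs. The alternative
reading (fraction of both lengths) is stricter; the shorter-interval form is
the most permissive symmetric choice and treats a nested anchor as fully
overlapping.

*Gap merging* joins intervals whose gap is ≤ `max_gap` (inclusive), matching
the `-d` semantics of common merge tools. Merging is idempotent and
order-independent; a merged cluster is the envelope of its members, which
are retained (with their genome ids) for presence counting.

*Liftover* uses equal-length aligned blocks (the chain-file abstraction).
Both endpoints are mapped independently; an interval whose endpoints land in
one block maps length-preserved; endpoints in different blocks keep the
envelope if they land on one chromosome in consistent order; anything else
returns an unmapped result with a reason code (`unaligned`,
`endpoint_unaligned`, `split_chromosome`, `inverted_order`, `chrom_absent`).

## Conservation categories

With presence count c of n genomes: core (c = n), softcore (c < n and
c/n ≥ 0.9), private (c = 1), dispensable (otherwise). The categories are
mutually exclusive and exhaustive; presence is counted over **distinct**
genomes, so one genome contributing two merged members counts once. Loop
clusters are single-linkage connected components of the pairwise
conservation relation — the minimal closure that makes clusters
well-defined when only a pairwise rule is given. Single linkage can chain:
A~B and B~C places A and C in one cluster even if A and C overlap by less
than half. On well-separated synthetic anchors this never triggers; on real
data chained clusters are visible as clusters whose anchor envelope is much
wider than one anchor.

## Insulation, boundaries, TADs

The insulation score of bin b with window w is the mean of the
w×w contact submatrix strictly upstream × strictly downstream of b (diamond
with the center bin excluded); it is undefined within w bins of the matrix
edge. The default is w = 2 at 40-kb bins. The normalized score is
log₂(IS / mean of valid IS); before the log, the ratio is floored at 1e-3
so that zero-contact windows stay finite while still ranking below every
real window (a window mean of exactly zero otherwise produces −∞ and breaks
prominence arithmetic).

Boundary candidates are local minima of the normalized score, with plateaus
of equal-value bins merged into one call. Boundary strength is the
topographic prominence of the minimum (depth relative to the lower of the
two enclosing maxima ranges, via `scipy.signal.find_peaks`). The strength
threshold is Li & Lee's minimum cross-entropy threshold computed on the
candidate strengths themselves — the iteration
t ← (μ_below − μ_above)/(ln μ_below − ln μ_above), converged at 1e-8
absolute, with non-positive inputs shifted by machine epsilon. Note that
scikit-image's `threshold_li` first shifts the data minimum to zero; the
two agree once the same shift is applied, and this equivalence is what the
test suite checks.

TADs are the spans between adjacent boundary intervals; the two
chromosome-end spans are emitted flagged `partial`, so k boundaries always
yield k+1 spans.

## Compartments and map resolution

Compartment calling masks zero-marginal bins, divides each matrix entry by
its diagonal mean (observed/expected), takes the Pearson correlation matrix
and its leading eigenvector, and orients the sign so the eigenvector
correlates positively with a per-bin orientation track (gene density in
practice — active chromatin is gene-dense). Positive entries are A;
negative **and exact zeros** are B (a deterministic tie-break, flagged here
rather than hidden). Contiguous same-label bins merge into compartment
intervals; calls are invariant to global matrix scaling.

Map resolution is the smallest bin size at which at least 80% of bins
(inclusive) accumulate ≥ 1,000 contacts; if none qualifies the largest bin
size is returned with a warning flag.

## LT-CREs, loop typing, TAD reorganization, boundary activity

An LT-CRE is an ATAC peak at least 2,000 bp (edge-to-point) from every TSS
that overlaps at least one loop anchor. A loop anchor is E if it overlaps an
LT-CRE — E takes precedence — else G if it overlaps the 2-kb window
immediately upstream of a TSS; loops are E-E, E-G, G-G, or unannotated if
either anchor is unlabeled.

TAD reorganization against a reference set: **stable** when exactly one
reference TAD overlaps the query reciprocally by ≥ 0.8 of both; **fusion**
when ≥ 2 reference TADs each cover ≥ 20% of the query and jointly ≥ 80%;
**neo** when reference TADs cover ≤ 50% of the query; otherwise
unclassified. These thresholds are conventions, exposed as parameters, not
measurements.

Boundary activity classes come from k-means (k = 3, 50 restarts, fixed
seed) on z-scored ATAC coverage, mean expression of overlapping genes, and
gene count in boundary ± 20 kb; clusters are relabeled
active/neutral/inactive by descending mean ATAC z-score, which makes the
labels permutation- and duplication-invariant.

## SV merging, mechanisms, hotspots, genotype QC

Merging follows the SURVIVOR parameterization max-distance 1000 /
min-callers 1 / type-agreement on / strand off / size-scaled distance off /
min-size 50: records below 50 bp are dropped (translocations, whose size is
undefined, are exempt), and two records link iff same chromosome, same
type, and both |Δstart| ≤ 1000 and |Δend| ≤ 1000. Clusters are connected
components; the emitted representative is the cluster **medoid** (minimum
summed breakpoint distance, ties by genome id then record id), which keeps
the output deterministic and input-order-free.

Mechanism classification fires the first matching rule in a fixed order:
VNTR (tandem-repeat coverage ≥ 0.8), TEI (TE coverage ≥ 0.8 with a dominant
family), NAHR (flanking homology ≥ 100 bp), FoSTeS/MMBIR (templated
switch), alt-EJ (junction microhomology 3–20 bp), NHEJ (microhomology
≤ 2 bp), else unassigned. The thresholds follow the Meerkat-style
conventions of assembly-based SV studies and are all parameters.

Hotspots: breakpoints (both ends of every SV) are counted in 100-kb
non-overlapping windows; a window is a hotspot when its count exceeds
mean + 2 SD over all genome windows (population SD; constant counts yield
no calls). A top-1% percentile rule is available as an alternative.

Genotype QC masks a call unless DP > 2 **and** GQ > 10 (strict), then drops
sites with missingness > 0.5 or minor-allele frequency < 0.05 computed on
non-missing alleles.

## Selection statistics and the bootstrap null

Fst is the Weir & Cockerham (1984) estimator for two populations: per-site
variance components a (among populations), b (among individuals within
populations), c (within individuals) from sample sizes, allele frequencies
and observed heterozygosity; θ̂ = a/(a+b+c), and the multi-site "weighted"
value is Σa/Σ(a+b+c). Sites monomorphic over both populations or with < 2
genotyped individuals in either population are excluded and counted. The
reported table clips Fst to [−0.05, 1]; the estimator itself is unclipped.

Per-site π uses the integer-count form alt·(n−alt)/C(n,2) over n
non-missing haplotypes — identical to 2p(1−p)·n/(n−1) but exact against
pairwise counting. Window π divides the site sum by the window length
(50-kb windows, 25-kb step by default).

Candidate screening requires Fst **and** Pi-ratio (π_pop1/π_pop2,
population 1 being the wild/reference population so sweeps in the
domesticated population inflate the ratio) both at or above their 95th
percentiles (linear-interpolation quantiles, cutoff ties included).
Ranking uses the Euclidean distance √(x² + y²) on min–max scaled Fst and
min–max scaled log₂ Pi-ratio; the scaling makes the two axes commensurate
and is exposed as a config choice since raw-axis ranking is equally
defensible.

The bootstrap coverage test holds the feature set fixed and relocates the
**regions**: each draw moves every region to a uniform start on a
chromosome sampled proportional to length (among chromosomes long enough to
hold it), overlaps among relocated regions permitted. Coverage is summed
covered bp over regions divided by summed region length. Empirical p-values
use the add-one convention (k+1)/(N+1), which cannot reach zero; N = 1,000
draws by default. Relocating regions rather than features is the literal
reading of a shuffled-regions null and is much cheaper (the feature union
is prefix-summed once, each draw costs O(R log F)).

## The synthetic-data generator

The generator defines the study conditions; its defaults are not tuning
knobs. It emulates: 15 genomes on a shared backbone; per-genome liftover
maps with 1–10 indels of 1–50 kb per chromosome (> 95% of the backbone
stays alignable); conservation classes drawn **first** with probabilities
0.30/0.13/0.29/0.28 (core/softcore/dispensable/private) and genome
membership sampled from the class band (softcore for n = 15 is exactly
c = 14; the generator errors out when a band is empty rather than silently
reassigning); per-genome coordinates obtained by pushing the backbone
position through the genome's map plus a jitter strictly below half the
relevant merge tolerance (15 kb for 40-kb boundary gaps, 200 bp for 500-bp
LT-CRE gaps, ±2 kb on 10-kb loop anchors, ±400 bp on SV breakpoints).
Cluster placements sit on grids spaced so that distinct clusters can never
merge under their rule; placements avoid indel regions of every genome so
liftover succeeds by construction. SV junction signatures (TE/TR coverage,
flank homology, microhomology, templated-switch flag) are planted directly
inside the intended rule region with all earlier rules explicitly out of
range — sequence is never simulated. SVs are emitted in backbone
coordinates, as merging operates in backbone space.

Contact matrices are block models: expected count `within` inside planted
TADs and `between` elsewhere, with Poisson counts by default (Gaussian or
noise-free optional), symmetrized from the upper triangle. Genotypes are
Hardy–Weinberg draws per population from given allele frequencies (a
Balding–Nichols-style helper generates frequency pairs at a target
divergence); DP ~ Poisson(20) and GQ ~ U(30, 99) by default, with an
optional fraction of deliberately low-quality calls. Capture tables plant
an exact number of MT-specific rows satisfying the differential rule by
construction, with background rows violating at least one condition.

Because generation is class-first and geometry respects the merge
tolerances, planted-class recovery is exact — this validates the
*bookkeeping* of the pipeline (liftover, merging, counting,
classification), not its robustness to real-data pathologies. What the
block model omits: distance-dependent contact decay, nested/overlapping
TADs, unbalanced coverage, reference bias, mosaic liftover failures,
segmental duplications that defeat 1:1 block maps, and LD structure in
genotypes. Passing benchmarks therefore demonstrate correctness of the
implemented rules under their own assumptions, and calibrated error rates
for the stochastic components, not performance on real chicken Hi-C.

## Benchmark problem sizes

The evaluation experiments (`panchrom3d.benchmarks`, driven by
`scripts/acceptance.py`) use: 1,000 clusters per feature kind across five
40-Mb chromosomes for classification exactness; 20 planted TADs per matrix,
within/between 5/1, Poisson noise, 40-kb bins, w = 2, 20 seeds, ±1-bin
matching for boundary recall/precision; 200 replicates × 500 null draws
(2,000 SVs, 50 regions of 40 kb on a 100-Mb genome) for bootstrap
calibration and 50 seeds × 10,000 SVs at depletion factor 0.3 for power;
100 random sites for the Fst oracle; 1,000 SVs with 10 planted +5-SD
outliers for the screen; 250 interactions (25% MT-specific) for the capture
check. These sizes keep a full run around half a minute on one core while
leaving the Monte Carlo estimates stable to well within the asserted
margins.

## Known limitations

- Loop clustering is O(pairs within anchor overlap); pathological inputs
  with thousands of mutually overlapping anchors degrade to quadratic.
- The bootstrap null relocates regions independently, so the spacing
  structure of the region set is not preserved.
- No matrix balancing (ICE) is applied; inputs are assumed comparable
  across bins.
- The Fst estimator is the two-population form; multi-population θ is out
  of scope.
- TRA records merge by breakpoints but are excluded from coverage-based
  statistics; their second breakend's chromosome is not modeled.
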