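"""Synthetic multi-genome pan datasets with planted ground truth.

The generator emulates the structure of a pan-3D genome study: N genomes
share a backbone coordinate system; each genome differs from the backbone by
a handful of indels (encoded as a block liftover map); features (TAD
boundaries, LT-CREs, chromatin loops, SVs, gene families) are planted as
cross-genome clusters whose conservation class (core / softcore /
dispensable / private) is drawn FIRST and genome membership sampled from it,
so downstream classification can be checked against exact truth.  Per-genome
coordinates are the backbone position pushed through that genome's map plus
a bounded jitter (below half the relevant merge gap).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnchoredPair,
    GenomeCoordinates,
    Interval,
    LiftoverBlock,
    LiftoverMap,
    PresenceMatrix,
)
from .sv import JunctionFeatures, SVRecord

CATEGORIES = ("core", "softcore", "dispensable", "private")

DEFAULT_CLASS_PROBS = {"core": 0.30, "softcore": 0.13, "dispensable": 0.29,
                       "private": 0.28}


# ---------------------------------------------------------------------------
# Configuration / truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the pan-dataset generator.

    Defaults mirror the study design: 15 genomes, conservation classes drawn
    with probabilities 0.30/0.13/0.29/0.28 (core/softcore/dispensable/
    private), 40-kb TAD boundaries merged at a 40-kb gap, 500-bp LT-CRE merge
    gap, 1-kb SV breakpoint merge distance; jitters sit strictly below half
    of each merge tolerance.
    """

    n_genomes: int = 15
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000})
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    n_gene_families: int = 1000
    n_boundaries: int = 50
    n_loops: int = 50
    n_ltcres: int = 100
    n_svs: int = 200
    boundary_depletion_factor: float = 1.0
    # feature geometry (bp)
    boundary_len: int = 40_000
    boundary_jitter: int = 15_000        # < 40 kb merge gap / 2
    ltcre_len: int = 400
    ltcre_jitter: int = 200              # < 500 bp merge gap / 2
    loop_anchor_len: int = 10_000
    loop_jitter: int = 2_000             # keeps anchor overlap > 0.5
    loop_span: int = 200_000
    sv_jitter: int = 400                 # < 1 kb merge distance / 2
    sv_size_range: tuple[int, int] = (50, 5000)
    sv_min_spacing: int = 10_000
    # per-genome indel model
    indels_per_chrom: tuple[int, int] = (1, 10)
    indel_size_range: tuple[int, int] = (1_000, 50_000)
    # populations
    pop_sizes: tuple[int, int] = (25, 25)
    fst_target: float = 0.2
    tad_size_bins: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.get(c, 0.0) for c in CATEGORIES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_probs must sum to 1 (got {total})")
        for name in ("n_gene_families", "n_boundaries", "n_loops", "n_ltcres",
                     "n_svs", "n_genomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.class_probs.get("softcore", 0) > 0 and not _softcore_band(self.n_genomes):
            raise ValueError(
                f"softcore band empty for n_genomes={self.n_genomes}; "
                "need ceil(0.9 n) <= n - 1")
        if self.class_probs.get("dispensable", 0) > 0 and not _dispensable_band(
                self.n_genomes):
            raise ValueError(
                f"dispensable band empty for n_genomes={self.n_genomes}")


def _softcore_band(n: int) -> list[int]:
    lo = math.ceil(0.9 * n)
    return list(range(lo, n))          # c < n with c/n >= 0.9


def _dispensable_band(n: int) -> list[int]:
    hi = math.ceil(0.9 * n) - 1
    return list(range(2, hi + 1))      # 2 <= c, below the softcore band


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset."""

    classes: dict[str, list[str]] = field(default_factory=dict)
    cluster_positions: dict[str, list[Interval]] = field(default_factory=dict)
    sv_mechanisms: dict[str, str] = field(default_factory=dict)
    depleted_regions: list[Interval] = field(default_factory=list)
    boundary_positions: list[Interval] = field(default_factory=list)


@dataclass
class SimDataset:
    config: SimConfig
    backbone: GenomeCoordinates
    genome_ids: list[str]
    maps: dict[str, LiftoverMap]            # genome -> backbone direction
    boundaries: dict[str, list[Interval]]   # per-genome, genome coordinates
    ltcres: dict[str, list[Interval]]
    loops: dict[str, list[AnchoredPair]]
    svs: list[SVRecord]                     # backbone coordinates
    families: PresenceMatrix
    truth: SimTruth


# ---------------------------------------------------------------------------
# Indel-shift liftover maps
# ---------------------------------------------------------------------------

def _simulate_genome_map(backbone: GenomeCoordinates, cfg: SimConfig,
                         rng: np.random.Generator):
    """One genome's indel set.

    Returns (backbone->genome map, avoid spans).  Avoid spans are backbone
    regions features must not touch: deleted backbone segments (unaligned)
    plus insertion points (where the genome gains sequence, so a straddling
    feature would not lift back length-preserved).
    """
    blocks: list[LiftoverBlock] = []
    avoid: list[Interval] = []
    for chrom, length in backbone.chrom_sizes.items():
        k = int(rng.integers(cfg.indels_per_chrom[0], cfg.indels_per_chrom[1] + 1))
        sizes = rng.integers(cfg.indel_size_range[0], cfg.indel_size_range[1] + 1,
                             size=k)
        kinds = rng.random(k) < 0.5     # True: deletion from the genome
        # one event per equal chromosome segment keeps events disjoint
        seg = length // (k + 1)
        if seg <= 2 * cfg.indel_size_range[1]:
            raise ValueError("chromosome too short for the indel model")
        positions = [seg * (i + 1) + int(rng.integers(0, seg // 4))
                     for i in range(k)]
        src = 0      # backbone cursor
        tgt = 0      # genome cursor
        for pos, size, is_del in zip(positions, sizes, kinds):
            pos, size = int(pos), int(size)
            blocks.append(LiftoverBlock(chrom, src, pos, chrom, tgt))
            tgt += pos - src
            if is_del:
                avoid.append(Interval(chrom, pos, pos + size))
                src = pos + size
            else:
                avoid.append(Interval(chrom, pos, pos + 1))
                tgt += size
                src = pos
        blocks.append(LiftoverBlock(chrom, src, length, chrom, tgt))
    return LiftoverMap(blocks), avoid


# ---------------------------------------------------------------------------
# Class-first membership sampling
# ---------------------------------------------------------------------------

def _draw_membership(category: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean membership vector over n genomes consistent with a category."""
    if category == "core":
        count = n
    elif category == "private":
        count = 1
    elif category == "softcore":
        band = _softcore_band(n)
        count = int(rng.choice(band))
    elif category == "dispensable":
        band = _dispensable_band(n)
        count = int(rng.choice(band))
    else:
        raise ValueError(f"unknown category {category!r}")
    members = np.zeros(n, dtype=bool)
    members[rng.choice(n, size=count, replace=False)] = True
    return members


def _place_slots(backbone: GenomeCoordinates, forbidden: dict[str, np.ndarray],
                 n: int | None, width: int, spacing: int,
                 pad: int) -> list[tuple[str, int]]:
    """Grid positions avoiding forbidden (indel) backbone spans.

    ``n=None`` returns every available slot.
    """
    slots: list[tuple[str, int]] = []
    for chrom, length in backbone.chrom_sizes.items():
        fb = forbidden.get(chrom, np.empty((0, 2), dtype=np.int64))
        pos = spacing
        while pos + width + pad < length and (n is None or len(slots) < n):
            lo, hi = pos - pad, pos + width + pad
            # overlap with any forbidden span?
            i = np.searchsorted(fb[:, 0], hi)
            clash = i > 0 and fb[:i, 1].max(initial=-1) > lo
            if not clash:
                slots.append((chrom, pos))
            pos += spacing
        if n is not None and len(slots) >= n:
            break
    if n is not None and len(slots) < n:
        raise ValueError(
            f"genome too small: placed {len(slots)}/{n} clusters at "
            f"spacing {spacing}; enlarge chrom_sizes")
    return slots


# ---------------------------------------------------------------------------
# Main pan-dataset generator
# ---------------------------------------------------------------------------

def simulate_pan_dataset(config: SimConfig) -> SimDataset:
    """Generate per-genome features, liftover maps, presence matrix and truth."""
    rng = np.random.default_rng(config.seed)
    backbone = GenomeCoordinates(config.chrom_sizes)
    n = config.n_genomes
    genome_ids = [f"G{i + 1:02d}" for i in range(n)]

    fwd_maps: dict[str, LiftoverMap] = {}   # backbone -> genome
    maps: dict[str, LiftoverMap] = {}       # genome -> backbone (emitted)
    forbidden_spans: dict[str, list[tuple[int, int]]] = {}
    for gid in genome_ids:
        fwd, unaligned = _simulate_genome_map(backbone, config, rng)
        fwd_maps[gid] = fwd
        maps[gid] = fwd.invert()
        for iv in unaligned:
            forbidden_spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    forbidden = {
        c: np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
        for c, spans in forbidden_spans.items()
    }

    truth = SimTruth()
    probs = np.array([config.class_probs.get(c, 0.0) for c in CATEGORIES])

    # --- gene families: presence matrix only (class-first) ------------------
    fam_classes = [CATEGORIES[i] for i in rng.choice(len(CATEGORIES),
                   size=config.n_gene_families, p=probs)]
    fam_presence = np.stack([_draw_membership(c, n, rng) for c in fam_classes])
    families = PresenceMatrix(fam_presence, genome_ids,
                              [f"fam_{i:05d}" for i in range(config.n_gene_families)])
    truth.classes["gene_family"] = fam_classes

    def _per_genome_interval(gid: str, chrom: str, start: int, width: int,
                             jitter: int) -> Interval:
        hit = fwd_maps[gid].map_position(chrom, start)
        assert hit is not None, "slot placement must avoid unaligned spans"
        tchrom, tstart = hit
        delta = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        return Interval(tchrom, tstart + delta, tstart + delta + width,
                        genome_id=gid)

    # --- interval-feature kinds (boundaries, LT-CREs) ----------------------
    def _plant_interval_kind(kind: str, n_clusters: int, width: int,
                             jitter: int, spacing: int):
        slots = _place_slots(backbone, forbidden, n_clusters, width, spacing,
                             pad=jitter + 100)
        classes = [CATEGORIES[i] for i in rng.choice(len(CATEGORIES),
                   size=n_clusters, p=probs)]
        per_genome: dict[str, list[Interval]] = {g: [] for g in genome_ids}
        positions = []
        for (chrom, pos), cat in zip(slots, classes):
            members = _draw_membership(cat, n, rng)
            positions.append(Interval(chrom, pos, pos + width))
            for gi in np.flatnonzero(members):
                gid = genome_ids[gi]
                per_genome[gid].append(
                    _per_genome_interval(gid, chrom, pos, width, jitter))
        truth.classes[kind] = classes
        truth.cluster_positions[kind] = positions
        return per_genome

    boundary_spacing = config.boundary_len + 2 * config.boundary_jitter + 40_000 + 20_000
    boundaries = _plant_interval_kind(
        "boundary", config.n_boundaries, config.boundary_len,
        config.boundary_jitter, boundary_spacing)
    ltcre_spacing = config.ltcre_len + 2 * config.ltcre_jitter + 500 + 1_500
    ltcres = _plant_interval_kind(
        "ltcre", config.n_ltcres, config.ltcre_len, config.ltcre_jitter,
        ltcre_spacing)
    truth.boundary_positions = truth.cluster_positions["boundary"]

    # --- loops --------------------------------------------------------------
    anchor_w = config.loop_anchor_len
    loop_spacing = anchor_w + 2 * config.loop_jitter + anchor_w  # disjoint anchors
    loop_slots = _place_slots(
        backbone, forbidden, config.n_loops, anchor_w + config.loop_span,
        loop_spacing, pad=config.loop_jitter + 100)
    loop_classes = [CATEGORIES[i] for i in rng.choice(len(CATEGORIES),
                    size=config.n_loops, p=probs)]
    loops: dict[str, list[AnchoredPair]] = {g: [] for g in genome_ids}
    loop_positions = []
    for (chrom, pos), cat in zip(loop_slots, loop_classes):
        members = _draw_membership(cat, n, rng)
        a2 = pos + config.loop_span
        loop_positions.append(Interval(chrom, pos, a2 + anchor_w))
        for gi in np.flatnonzero(members):
            gid = genome_ids[gi]
            loops[gid].append(AnchoredPair(
                _per_genome_interval(gid, chrom, pos, anchor_w, config.loop_jitter),
                _per_genome_interval(gid, chrom, a2, anchor_w, config.loop_jitter),
                score=float(rng.uniform(1, 10)), genome_id=gid))
    truth.classes["loop"] = loop_classes
    truth.cluster_positions["loop"] = loop_positions

    # --- SVs (backbone coordinates, merge-ready) ----------------------------
    svs, sv_classes, sv_positions = _plant_svs(config, backbone, forbidden,
                                               truth, genome_ids, rng, probs)
    truth.classes["sv"] = sv_classes
    truth.cluster_positions["sv"] = sv_positions
    if config.boundary_depletion_factor != 1.0:
        truth.depleted_regions = list(truth.boundary_positions)

    return SimDataset(config, backbone, genome_ids, maps, boundaries, ltcres,
                      loops, svs, families, truth)


def _plant_svs(config, backbone, forbidden, truth, genome_ids, rng, probs):
    n = config.n_genomes
    max_size = config.sv_size_range[1]
    spacing = max(config.sv_min_spacing,
                  max_size + 2 * config.sv_jitter + 1000 + 500)
    f = config.boundary_depletion_factor
    boundary_regions = {
        c: np.array([(iv.start, iv.end) for iv in truth.boundary_positions
                     if iv.chrom == c], dtype=np.int64).reshape(-1, 2)
        for c in backbone.chroms
    }
    # oversample slots, then thin inside boundary regions with probability f
    all_slots = _place_slots(backbone, forbidden, None, max_size, spacing,
                             pad=config.sv_jitter + 100)
    slots = []
    for chrom, pos in all_slots:
        br = boundary_regions.get(chrom)
        inside = br is not None and br.size and bool(
            ((br[:, 0] <= pos) & (pos < br[:, 1])).any())
        if not inside or rng.random() < f:
            slots.append((chrom, pos))
        if len(slots) == config.n_svs:
            break
    if len(slots) < config.n_svs:
        raise ValueError("genome too small for requested n_svs")
    classes = [CATEGORIES[i] for i in rng.choice(len(CATEGORIES),
               size=config.n_svs, p=probs)]
    type_probs = {"DEL": 0.4, "INS": 0.4, "INV": 0.1, "DUP": 0.1}
    mech_pool = ("TEI", "NHEJ", "VNTR", "FoSTeS_MMBIR", "NAHR", "alt_EJ")
    svs: list[SVRecord] = []
    positions = []
    for ci, ((chrom, pos), cat) in enumerate(zip(slots, classes)):
        members = _draw_membership(cat, n, rng)
        sv_type = str(rng.choice(list(type_probs), p=list(type_probs.values())))
        size = int(rng.integers(config.sv_size_range[0], config.sv_size_range[1] + 1))
        mech = str(rng.choice(mech_pool))
        end = pos + 1 if sv_type == "INS" else pos + size
        positions.append(Interval(chrom, pos, max(end, pos + 1)))
        for gi in np.flatnonzero(members):
            gid = genome_ids[gi]
            delta = int(rng.integers(-config.sv_jitter, config.sv_jitter + 1))
            s = pos + delta
            e = s + 1 if sv_type == "INS" else s + size
            sv_id = f"sv_{ci:05d}_{gid}"
            svs.append(SVRecord(chrom, s, e, sv_type, size, genome_id=gid,
                                sv_id=sv_id,
                                junction=plant_junction(mech, rng)))
            truth.sv_mechanisms[sv_id] = mech
    return svs, classes, positions


def plant_junction(mechanism: str, rng: np.random.Generator) -> JunctionFeatures:
    """Junction signature guaranteed to fire exactly the intended rule.

    Earlier rules in the classifier's fixed order are explicitly placed
    outside their trigger regions.
    """
    base = dict(te_cov=float(rng.uniform(0, 0.5)), te_family="",
                tr_cov=float(rng.uniform(0, 0.5)),
                flank_hom=int(rng.integers(0, 50)),
                microhom=int(rng.integers(0, 3)), templated_switch=False)
    if mechanism == "VNTR":
        base["tr_cov"] = float(rng.uniform(0.8, 1.0))
    elif mechanism == "TEI":
        base["te_cov"] = float(rng.uniform(0.8, 1.0))
        base["te_family"] = str(rng.choice(["LTR/ERV", "LINE/CR1", "SINE"]))
    elif mechanism == "NAHR":
        base["flank_hom"] = int(rng.integers(100, 500))
    elif mechanism == "FoSTeS_MMBIR":
        base["templated_switch"] = True
        base["flank_hom"] = int(rng.integers(0, 100))
    elif mechanism == "alt_EJ":
        base["microhom"] = int(rng.integers(3, 21))
        base["flank_hom"] = int(rng.integers(0, 100))
    elif mechanism == "NHEJ":
        base["microhom"] = int(rng.integers(0, 3))
        base["flank_hom"] = int(rng.integers(0, 100))
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return JunctionFeatures(**base)


# ---------------------------------------------------------------------------
# SV placement for coverage/bootstrap experiments
# ---------------------------------------------------------------------------

def simulate_sv_placement(
    genome: GenomeCoordinates,
    regions: Sequence[Interval],
    n_svs: int,
    depletion_factor: float = 1.0,
    size_range: tuple[int, int] = (50, 5000),
    seed: int | None = None,
) -> list[Interval]:
    """Place SV spans uniformly, thinned inside ``regions`` by the factor.

    An SV whose start breakpoint falls inside a region is accepted with
    probability ``depletion_factor``; elsewhere always.  The expected SV
    density (hence coverage) inside regions is therefore ``factor`` times the
    genome background.  Overlaps between SVs are permitted.
    """
    if not 0.0 <= depletion_factor <= 1.0:
        raise ValueError("depletion_factor must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    region_edges = {
        c: np.array(sorted((iv.start, iv.end) for iv in regions
                           if iv.chrom == c), dtype=np.int64).reshape(-1, 2)
        for c in chroms
    }
    out: list[Interval] = []
    max_size = size_range[1]
    while len(out) < n_svs:
        batch = max(1024, 2 * (n_svs - len(out)))
        ci = rng.choice(len(chroms), size=batch, p=p)
        sizes = rng.integers(size_range[0], size_range[1] + 1, size=batch)
        u = rng.random(batch)
        accept_u = rng.random(batch)
        for k in range(batch):
            chrom = chroms[ci[k]]
            length = genome[chrom]
            start = int(u[k] * (length - max_size))
            br = region_edges[chrom]
            inside = br.size and bool(((br[:, 0] <= start) & (start < br[:, 1])).any())
            if inside and accept_u[k] >= depletion_factor:
                continue
            out.append(Interval(chrom, start, start + int(sizes[k])))
            if len(out) == n_svs:
                break
    return out


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def plant_tads(chrom: str, n_tads: int, bin_size: int,
               size_bins: tuple[int, int] = (5, 15),
               seed: int | None = None) -> list[Interval]:
    """Tile a chromosome with ``n_tads`` adjacent domains of random bin sizes."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_bins[0], size_bins[1] + 1, size=n_tads)
    edges = np.concatenate([[0], np.cumsum(sizes)]) * bin_size
    return [Interval(chrom, int(edges[i]), int(edges[i + 1]))
            for i in range(n_tads)]


def simulate_contact_matrix(
    tads: Sequence[Interval],
    bin_size: int,
    within: float,
    between: float,
    noise: str = "poisson",
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Block contact matrix: expected ``within`` inside planted TADs, else
    ``between``; Poisson or truncated-Gaussian counts, symmetric by
    construction.  ``noise='none'`` (or a zero-sd Gaussian) returns the exact
    mean matrix."""
    from .chromatin import ContactMatrix   # late import avoids a cycle

    if within <= between or between < 0:
        raise ValueError("need within > between >= 0")
    tads = sorted(tads, key=lambda t: t.start)
    chrom = tads[0].chrom
    edges = [tads[0].start]
    for t in tads:
        if t.start != edges[-1]:
            raise ValueError("TADs must tile the chromosome without gaps")
        if t.length < 2 * bin_size:
            raise ValueError("TAD shorter than 2 bins")
        if t.length % bin_size:
            raise ValueError("TAD length must be a bin multiple")
        edges.append(t.end)
    n_bins = (edges[-1] - edges[0]) // bin_size
    mean = np.full((n_bins, n_bins), float(between))
    for t in tads:
        a, b = t.start // bin_size, t.end // bin_size
        mean[a:b, a:b] = within
    rng = np.random.default_rng(seed)
    if noise == "none":
        m = mean.copy()
    elif noise == "poisson":
        upper = rng.poisson(mean).astype(float)
        m = np.triu(upper) + np.triu(upper, 1).T
    elif noise == "gaussian":
        upper = np.clip(mean + rng.normal(0.0, noise_sd, mean.shape), 0, None)
        m = np.triu(upper) + np.triu(upper, 1).T
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=m)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid dosage matrix (sites x samples) with DP/GQ and pop labels."""

    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    sample_pops: np.ndarray    # 0 or 1 per sample

    def pop_slices(self) -> tuple[np.ndarray, np.ndarray]:
        return self.gt[:, self.sample_pops == 0], self.gt[:, self.sample_pops == 1]


def simulate_genotypes(
    pop_sizes: tuple[int, int],
    allele_freqs: np.ndarray,
    seed: int | None = None,
    dp_mean: float = 20.0,
    gq_range: tuple[int, int] = (30, 99),
    frac_lowqual: float = 0.0,
) -> GenotypeTable:
    """Hardy-Weinberg diploid draws per population.

    ``allele_freqs`` has shape (n_sites, 2): alt frequency per population.
    ``frac_lowqual`` forces a fraction of calls under the DP/GQ QC thresholds
    (DP <= 2 or GQ <= 10) to exercise filtering.
    """
    rng = np.random.default_rng(seed)
    freqs = np.atleast_2d(np.asarray(allele_freqs, dtype=float))
    if freqs.shape[1] != 2:
        raise ValueError("allele_freqs must be (n_sites, 2)")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    n_sites = freqs.shape[0]
    n1, n2 = pop_sizes
    gt = np.empty((n_sites, n1 + n2), dtype=np.int8)
    gt[:, :n1] = rng.binomial(2, freqs[:, [0]], size=(n_sites, n1))
    gt[:, n1:] = rng.binomial(2, freqs[:, [1]], size=(n_sites, n2))
    dp = rng.poisson(dp_mean, size=gt.shape).astype(np.int32)
    gq = rng.integers(gq_range[0], gq_range[1] + 1, size=gt.shape).astype(np.int32)
    if frac_lowqual > 0:
        low = rng.random(gt.shape) < frac_lowqual
        which = rng.random(gt.shape) < 0.5
        dp[low & which] = rng.integers(0, 3)     # DP <= 2 fails DP > 2
        gq[low & ~which] = rng.integers(0, 11)   # GQ <= 10 fails GQ > 10
    pops = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    return GenotypeTable(gt, dp, gq, pops)


def divergent_allele_freqs(n_sites: int, fst_target: float,
                           seed: int | None = None) -> np.ndarray:
    """Per-pop alt frequencies under a Balding-Nichols-style divergence model."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    if fst_target <= 0:
        return np.column_stack([p, p])
    a = p * (1 - fst_target) / fst_target
    b = (1 - p) * (1 - fst_target) / fst_target
    return np.column_stack([rng.beta(a, b), rng.beta(a, b)])


# ---------------------------------------------------------------------------
# Capture Hi-C tables
# ---------------------------------------------------------------------------

def simulate_capture_table(
    n_interactions: int,
    frac_mt_specific: float,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Paired WT/MT interaction scores with planted MT-specific rows.

    MT-specific rows satisfy (MT >= 3, WT < 3, MT - WT > 3) by construction;
    background rows violate at least one condition.  Returns the table and a
    boolean truth mask.
    """
    if not 0.0 <= frac_mt_specific <= 1.0:
        raise ValueError("frac_mt_specific must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_true = int(round(frac_mt_specific * n_interactions))
    truth = np.zeros(n_interactions, dtype=bool)
    truth[:n_true] = True
    wt = np.empty(n_interactions)
    mt = np.empty(n_interactions)
    wt[:n_true] = rng.uniform(0.0, 2.5, n_true)
    mt[:n_true] = wt[:n_true] + 3.0 + rng.uniform(0.1, 6.0, n_true)
    n_bg = n_interactions - n_true
    kind = rng.integers(0, 3, n_bg)
    wt_bg = np.where(kind == 0, rng.uniform(0.0, 2.9, n_bg),       # both low
             np.where(kind == 1, rng.uniform(3.0, 8.0, n_bg),       # both sig
                      rng.uniform(6.5, 10.0, n_bg)))                # WT-enhanced
    mt_bg = np.where(kind == 0, np.minimum(wt_bg + rng.uniform(0, 2.9, n_bg), 2.9),
             np.where(kind == 1, wt_bg + rng.uniform(-2.5, 2.5, n_bg),
                      rng.uniform(0.0, 2.9, n_bg)))
    wt[n_true:] = wt_bg
    mt[n_true:] = np.clip(mt_bg, 0.0, None)
    perm = rng.permutation(n_interactions)
    wt, mt, truth = wt[perm], mt[perm], truth[perm]
    bin_size = 10_000
    starts = np.arange(n_interactions) * bin_size
    df = pd.DataFrame({
        "bait_chrom": "chr1", "bait_start": 1_000_000, "bait_end": 1_010_000,
        "oe_chrom": "chr1", "oe_start": 2_000_000 + starts,
        "oe_end": 2_000_000 + starts + bin_size,
        "score_wt": wt, "score_mt": mt,
    })
    return df, truth
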