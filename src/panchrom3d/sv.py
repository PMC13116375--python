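"""Structural-variant toolkit.

Multi-genome SV merging (SURVIVOR-style: max breakpoint distance 1000 bp, type
agreement required, minimum size 50 bp), formation-mechanism classification
from junction signatures, breakpoint hotspot detection, SV-gene annotation,
and genotype-level quality filtering (DP > 2, GQ > 10, missingness, MAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeCoordinates, Interval

SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA")

MECHANISMS = ("TEI", "NHEJ", "VNTR", "FoSTeS_MMBIR", "NAHR", "alt_EJ", "unassigned")


@dataclass
class JunctionFeatures:
    """Breakpoint-junction signature used for mechanism inference.

    te_cov / tr_cov are the fractions of the SV covered by transposable
    elements / tandem repeats; flank_hom and microhom are homology lengths in
    bp at the flanks and the junction respectively.
    """

    te_cov: float = 0.0
    te_family: str = ""
    tr_cov: float = 0.0
    flank_hom: int = 0
    microhom: int = 0
    templated_switch: bool = False

    def __post_init__(self) -> None:
        for frac in (self.te_cov, self.tr_cov):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage fraction {frac} outside [0, 1]")


@dataclass
class SVRecord:
    """A typed structural variant with optional junction and genotype data.

    Insertions are points: ``end == start + 1`` and ``size`` is the inserted
    length. ``genotypes`` maps sample -> (gt, dp, gq) where gt is 0/1/2 dosage
    or None for missing.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    size: int
    genome_id: str = ""
    sv_id: str = ""
    junction: JunctionFeatures | None = None
    genotypes: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if self.sv_type == "INS":
            if self.end != self.start + 1:
                raise ValueError("INS records are points: end must equal start + 1")
        elif self.end <= self.start:
            raise ValueError("start must precede end")

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.start, self.end)

    def as_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end,
                        genome_id=self.genome_id, meta={"sv_id": self.sv_id})


@dataclass
class MechanismCall:
    sv_id: str
    mechanism: str
    rule_fired: str


@dataclass
class MergedSV:
    """A non-redundant SV cluster: medoid representative plus members."""

    representative: SVRecord
    members: list[SVRecord]

    @property
    def support_genomes(self) -> list[str]:
        return sorted({m.genome_id for m in self.members})

    @property
    def presence_count(self) -> int:
        return len(self.support_genomes)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_svs(
    svs: Sequence[SVRecord],
    max_dist: int = 1000,
    min_size: int = 50,
    require_type: bool = True,
) -> list[MergedSV]:
    """Merge SV calls across genomes into a non-redundant set.

    Two records link iff they share a chromosome, agree in type (when
    ``require_type``), and both breakpoints lie within ``max_dist`` of each
    other; clusters are connected components of the link graph. Records
    smaller than ``min_size`` are dropped first (translocations, whose size is
    undefined, are exempt). The representative is the cluster medoid — the
    member minimising the summed breakpoint distance to all others — with
    ties broken by genome id then record id.
    """
    kept = [s for s in svs if s.sv_type == "TRA" or s.size >= min_size]
    if not kept:
        return []
    order = sorted(range(len(kept)),
                   key=lambda i: (kept[i].chrom, kept[i].start, kept[i].end))
    uf = _UnionFind(len(kept))
    for oi in range(len(order)):
        i = order[oi]
        a = kept[i]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            b = kept[j]
            if b.chrom != a.chrom or b.start - a.start > max_dist:
                break
            if require_type and a.sv_type != b.sv_type:
                continue
            if abs(a.end - b.end) <= max_dist:
                uf.union(i, j)
    clusters: dict[int, list[SVRecord]] = {}
    for i, rec in enumerate(kept):
        clusters.setdefault(uf.find(i), []).append(rec)
    out = []
    for members in clusters.values():
        out.append(MergedSV(_medoid(members), sorted(
            members, key=lambda m: (m.genome_id, m.sv_id))))
    out.sort(key=lambda m: (m.representative.chrom, m.representative.start,
                            m.representative.end, m.representative.sv_type))
    return out


def _medoid(members: list[SVRecord]) -> SVRecord:
    def cost(m: SVRecord) -> tuple:
        d = sum(abs(m.start - o.start) + abs(m.end - o.end) for o in members)
        return (d, m.genome_id, m.sv_id)

    return min(members, key=cost)


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def classify_sv_mechanism(
    sv: SVRecord,
    tr_cov_min: float = 0.8,
    te_cov_min: float = 0.8,
    nahr_hom_min: int = 100,
    altej_microhom: tuple[int, int] = (3, 20),
    nhej_microhom_max: int = 2,
) -> MechanismCall:
    """Assign a formation mechanism from junction features, first rule wins.

    Rule order: VNTR (tandem-repeat coverage), TEI (transposable-element
    coverage with a dominant family), NAHR (long flanking homology),
    FoSTeS/MMBIR (templated switch), alt-EJ (microhomology 3-20 bp),
    NHEJ (microhomology <= 2 bp); otherwise unassigned.
    """
    j = sv.junction
    if j is None:
        return MechanismCall(sv.sv_id, "unassigned", "missing_junction")
    if j.tr_cov >= tr_cov_min:
        return MechanismCall(sv.sv_id, "VNTR", "tr_cov")
    if j.te_cov >= te_cov_min and j.te_family:
        return MechanismCall(sv.sv_id, "TEI", "te_cov")
    if j.flank_hom >= nahr_hom_min:
        return MechanismCall(sv.sv_id, "NAHR", "flank_hom")
    if j.templated_switch:
        return MechanismCall(sv.sv_id, "FoSTeS_MMBIR", "templated_switch")
    if altej_microhom[0] <= j.microhom <= altej_microhom[1]:
        return MechanismCall(sv.sv_id, "alt_EJ", "microhom")
    if j.microhom <= nhej_microhom_max:
        return MechanismCall(sv.sv_id, "NHEJ", "microhom")
    return MechanismCall(sv.sv_id, "unassigned", "no_rule")


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def sv_hotspots(
    svs: Sequence[SVRecord],
    genome: GenomeCoordinates,
    window: int = 100_000,
    step: int = 100_000,
    method: str = "mean2sd",
) -> tuple[list[Interval], pd.DataFrame]:
    """Breakpoint counts per sliding window plus called hotspot windows.

    Both ends of every SV count as breakpoints.  A window is a hotspot when
    its count exceeds mean + 2 SD of all windows genome-wide (``mean2sd``) or
    lies in the top 1% (``top1pct``).  Constant counts yield no calls.
    """
    rows = []
    by_chrom: dict[str, list[int]] = {c: [] for c in genome.chroms}
    for sv in svs:
        if sv.chrom in by_chrom:
            by_chrom[sv.chrom].extend(sv.breakpoints)
    for chrom, length in genome.chrom_sizes.items():
        pos = np.sort(np.asarray(by_chrom[chrom], dtype=np.int64))
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        counts = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left")
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(c)))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    counts = table["count"].to_numpy(dtype=float)
    if method == "mean2sd":
        sd = counts.std()  # population SD over all genome windows
        if sd == 0:
            threshold = np.inf
        else:
            threshold = counts.mean() + 2.0 * sd
    elif method == "top1pct":
        threshold = np.quantile(counts, 0.99) if counts.std() > 0 else np.inf
    else:
        raise ValueError(f"unknown hotspot method {method!r}")
    table["hotspot"] = table["count"] > threshold
    hotspots = [
        Interval(r.chrom, r.start, r.end, meta={"count": r.count})
        for r in table.itertuples()
        if r.hotspot
    ]
    return hotspots, table


# ---------------------------------------------------------------------------
# SV-gene annotation
# ---------------------------------------------------------------------------

def annotate_sv_genes(
    svs: Sequence[SVRecord],
    genes: Sequence[Interval],
    flank: int = 5000,
) -> pd.DataFrame:
    """Pair each SV with genes within ``flank`` bp of its breakpoints.

    A gene is paired when its span overlaps the closed window
    [breakpoint - flank, breakpoint + flank] of either breakpoint; genes
    overlapping the SV body itself are therefore always paired.
    """
    gene_order = sorted(range(len(genes)), key=lambda i: genes[i].start)
    rows = []
    for sv in svs:
        lo, hi = sv.start - flank, sv.end + flank
        for gi in gene_order:
            g = genes[gi]
            if g.chrom != sv.chrom:
                continue
            if g.start <= hi and g.end > lo:
                rows.append((sv.sv_id, sv.chrom, sv.start, sv.end, sv.sv_type,
                             g.meta.get("gene_id", f"gene_{gi}"), g.start, g.end))
    return pd.DataFrame(rows, columns=[
        "sv_id", "chrom", "sv_start", "sv_end", "sv_type",
        "gene_id", "gene_start", "gene_end"])


# ---------------------------------------------------------------------------
# Genotype filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_sites: int
    n_kept: int
    n_dropped_missing: int
    n_dropped_maf: int
    n_all_missing: int


def filter_genotyped_svs(
    gt: np.ndarray,
    dp: np.ndarray,
    gq: np.ndarray,
    dp_min: int = 2,
    gq_min: int = 10,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, FilterReport]:
    """Genotype-level QC then site-level missingness/MAF filtering.

    Calls are set missing unless DP > ``dp_min`` AND GQ > ``gq_min`` (strict,
    the graph-genotyping QC rule).  Sites are dropped when the missing
    fraction exceeds ``max_missing`` or the minor-allele frequency, computed
    on non-missing alleles, falls below ``min_maf``.

    Parameters are arrays of shape (n_sites, n_samples); ``gt`` holds alt
    dosages 0/1/2 with -1 for missing. Returns (kept-site mask, masked
    genotypes, report).
    """
    gt = np.asarray(gt)
    masked = np.where((np.asarray(dp) > dp_min) & (np.asarray(gq) > gq_min), gt, -1)
    n_sites, n_samples = masked.shape
    missing = masked < 0
    miss_frac = missing.mean(axis=1)
    non_missing = (~missing).sum(axis=1)
    alt = np.where(missing, 0, masked).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(non_missing > 0, alt / (2.0 * non_missing), np.nan)
    maf = np.minimum(af, 1.0 - af)
    all_missing = non_missing == 0
    ok_missing = ~all_missing & (miss_frac <= max_missing)
    ok_maf = ok_missing & (maf >= min_maf)
    keep = ok_maf
    report = FilterReport(
        n_sites=n_sites,
        n_kept=int(keep.sum()),
        n_dropped_missing=int((~ok_missing & ~all_missing).sum()),
        n_dropped_maf=int((ok_missing & ~ok_maf).sum()),
        n_all_missing=int(all_missing.sum()),
    )
    return keep, masked, report
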