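"""Pan-genome conservation classification.

Core / softcore / dispensable / private categories across genomes for gene
families, SVs, TAD boundaries, chromatin loops and LT-CREs; pan/core
accumulation curves; A/B compartment conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnchoredPair,
    Interval,
    LiftoverMap,
    PresenceMatrix,
    liftover,
    merge_with_gap,
    reciprocal_overlap_fraction,
)
from .sv import MergedSV

CATEGORIES = ("core", "softcore", "dispensable", "private")

#: merge gaps per feature kind (bp)
DEFAULT_MAX_GAP = {"boundary": 40_000, "ltcre": 500}


def classify_pan_category(c: int, n: int, softcore_frac: float = 0.9) -> str:
    """Conservation category from presence count c of n genomes.

    core: all genomes; softcore: not all but >= 90%; private: exactly one;
    dispensable: everything else.  Categories are mutually exclusive.
    """
    if not 1 <= c <= n:
        raise ValueError(f"presence count {c} outside [1, {n}]")
    if c == n:
        return "core"
    if c / n >= softcore_frac:
        return "softcore"
    if c == 1:
        return "private"
    return "dispensable"


@dataclass
class PanCluster:
    cluster_id: str
    feature_kind: str
    members: dict[str, list] = field(default_factory=dict)
    presence_count: int = 0
    n_genomes: int = 0
    category: str = ""
    backbone_span: Interval | None = None
    anchor2_span: Interval | None = None   # loops only


@dataclass
class CompartmentCall:
    region: Interval
    statuses: dict[str, str]
    pan_status: str    # conservative_A / conservative_B / variable


# ---------------------------------------------------------------------------
# Liftover of per-genome features to the backbone
# ---------------------------------------------------------------------------

def lift_features(
    features_by_genome: Mapping[str, Sequence[Interval]],
    maps: Mapping[str, LiftoverMap],
) -> tuple[dict[str, list[Interval]], dict[str, int]]:
    """Lift each genome's features through its map; unmapped features are
    excluded and counted per genome."""
    lifted: dict[str, list[Interval]] = {}
    unmapped: dict[str, int] = {}
    for gid, feats in features_by_genome.items():
        out = []
        dropped = 0
        for iv in feats:
            res = liftover(iv, maps[gid])
            if res.mapped:
                mapped = res.interval
                mapped.genome_id = gid or mapped.genome_id
                out.append(mapped)
            else:
                dropped += 1
        lifted[gid] = out
        unmapped[gid] = dropped
    return lifted, unmapped


def lift_loops(
    loops_by_genome: Mapping[str, Sequence[AnchoredPair]],
    maps: Mapping[str, LiftoverMap],
) -> tuple[dict[str, list[AnchoredPair]], dict[str, int]]:
    """Lift both anchors of each loop; loops with an unmapped anchor are
    excluded and counted."""
    lifted: dict[str, list[AnchoredPair]] = {}
    unmapped: dict[str, int] = {}
    for gid, loops in loops_by_genome.items():
        out = []
        dropped = 0
        for loop in loops:
            r1 = liftover(loop.anchor1, maps[gid])
            r2 = liftover(loop.anchor2, maps[gid])
            if r1.mapped and r2.mapped:
                out.append(AnchoredPair(r1.interval, r2.interval,
                                        score=loop.score, genome_id=gid))
            else:
                dropped += 1
        lifted[gid] = out
        unmapped[gid] = dropped
    return lifted, unmapped


# ---------------------------------------------------------------------------
# Interval-feature clustering (boundaries, LT-CREs, generic BED features)
# ---------------------------------------------------------------------------

def cluster_lifted_intervals(
    features_by_genome: Mapping[str, Sequence[Interval]],
    max_gap: int,
    feature_kind: str = "boundary",
) -> list[PanCluster]:
    """Pool backbone-coordinate features, merge with the kind's gap, and
    classify each merged cluster by its distinct-genome presence count."""
    n_genomes = len(features_by_genome)
    pooled: list[Interval] = []
    for gid, feats in features_by_genome.items():
        for iv in feats:
            if not iv.genome_id:
                iv = Interval(iv.chrom, iv.start, iv.end, genome_id=gid,
                              meta=iv.meta)
            pooled.append(iv)
    merged = merge_with_gap(pooled, max_gap)
    clusters = []
    for i, env in enumerate(merged):
        members: dict[str, list] = {}
        for m in env.meta["members"]:
            members.setdefault(m.genome_id, []).append(m)
        c = len(members)
        clusters.append(PanCluster(
            cluster_id=f"{feature_kind}_{i:05d}",
            feature_kind=feature_kind,
            members=members,
            presence_count=c,
            n_genomes=n_genomes,
            category=classify_pan_category(c, n_genomes),
            backbone_span=Interval(env.chrom, env.start, env.end),
        ))
    return clusters


# ---------------------------------------------------------------------------
# Loop clustering
# ---------------------------------------------------------------------------

def cluster_loops(
    loops_by_genome: Mapping[str, Sequence[AnchoredPair]],
    min_frac: float = 0.5,
) -> list[PanCluster]:
    """Single-linkage clusters of loops conserved across genomes.

    Two loops link iff their anchor1s AND anchor2s each overlap reciprocally
    by more than ``min_frac`` (strict, fraction of the shorter anchor).
    Clusters are connected components; categories follow the distinct-genome
    presence count.
    """
    n_genomes = len(loops_by_genome)
    flat: list[AnchoredPair] = []
    for gid, loops in loops_by_genome.items():
        for loop in loops:
            if not loop.genome_id:
                loop.genome_id = gid
            flat.append(loop)
    order = sorted(range(len(flat)),
                   key=lambda i: (flat[i].anchor1.chrom, flat[i].anchor1.start))
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for oi in range(len(order)):
        i = order[oi]
        a = flat[i]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            b = flat[j]
            if (b.anchor1.chrom != a.anchor1.chrom
                    or b.anchor1.start >= a.anchor1.end):
                break
            if a.anchor2.chrom != b.anchor2.chrom:
                continue
            if (reciprocal_overlap_fraction(a.anchor1, b.anchor1) > min_frac
                    and reciprocal_overlap_fraction(a.anchor2, b.anchor2) > min_frac):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[AnchoredPair]] = {}
    for i, loop in enumerate(flat):
        groups.setdefault(find(i), []).append(loop)
    clusters = []
    for k, members_list in enumerate(sorted(
            groups.values(),
            key=lambda g: (g[0].anchor1.chrom, min(x.anchor1.start for x in g)))):
        members: dict[str, list] = {}
        for loop in members_list:
            members.setdefault(loop.genome_id, []).append(loop)
        c = len(members)
        a1 = _envelope_of([m.anchor1 for m in members_list])
        a2 = _envelope_of([m.anchor2 for m in members_list])
        clusters.append(PanCluster(
            cluster_id=f"loop_{k:05d}", feature_kind="loop", members=members,
            presence_count=c, n_genomes=n_genomes,
            category=classify_pan_category(c, n_genomes),
            backbone_span=a1, anchor2_span=a2))
    return clusters


def _envelope_of(ivs: Sequence[Interval]) -> Interval:
    return Interval(ivs[0].chrom, min(i.start for i in ivs),
                    max(i.end for i in ivs))


# ---------------------------------------------------------------------------
# Pan-SV classification
# ---------------------------------------------------------------------------

def classify_pan_svs(merged: Sequence[MergedSV], n_genomes: int) -> list[PanCluster]:
    """Pan categories for a merged (non-redundant) SV set."""
    clusters = []
    for i, m in enumerate(merged):
        rep = m.representative
        members: dict[str, list] = {}
        for rec in m.members:
            members.setdefault(rec.genome_id, []).append(rec)
        c = len(members)
        clusters.append(PanCluster(
            cluster_id=f"sv_{i:05d}", feature_kind="sv", members=members,
            presence_count=c, n_genomes=n_genomes,
            category=classify_pan_category(c, n_genomes),
            backbone_span=Interval(rep.chrom, rep.start, max(rep.end, rep.start + 1)),
        ))
    return clusters


# ---------------------------------------------------------------------------
# Accumulation curves
# ---------------------------------------------------------------------------

def accumulation_curves(
    pm: PresenceMatrix,
    n_orders: int = 100,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Pan/core set sizes as genomes are added in random orders.

    Pan size at step k = clusters present in >= 1 of the first k genomes;
    core size = clusters present in all first k.  Returns per-order arrays
    plus mean and SD across orders.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    presence = pm.presence
    n = pm.n_genomes
    pan = np.empty((n_orders, n), dtype=np.int64)
    core = np.empty((n_orders, n), dtype=np.int64)
    for o in range(n_orders):
        order = rng.permutation(n)
        cum_any = np.logical_or.accumulate(presence[:, order], axis=1)
        cum_all = np.logical_and.accumulate(presence[:, order], axis=1)
        pan[o] = cum_any.sum(axis=0)
        core[o] = cum_all.sum(axis=0)
    return {
        "pan": pan, "core": core,
        "pan_mean": pan.mean(axis=0), "pan_sd": pan.std(axis=0),
        "core_mean": core.mean(axis=0), "core_sd": core.std(axis=0),
    }


# ---------------------------------------------------------------------------
# Compartment conservation
# ---------------------------------------------------------------------------

def compare_compartment_status(
    status: pd.DataFrame,
    regions: Sequence[Interval] | None = None,
    max_missing: float = 0.5,
) -> tuple[list[CompartmentCall], int]:
    """Pan-status of orthologous regions from per-genome A/B calls.

    ``status`` is regions x genomes with values 'A'/'B' (NaN where the region
    is unmappable).  All-A -> conservative_A, all-B -> conservative_B, else
    variable.  Regions missing in more than ``max_missing`` of genomes are
    excluded and counted.
    """
    calls = []
    excluded = 0
    for i, (_, row) in enumerate(status.iterrows()):
        vals = row.dropna()
        if len(vals) < len(row) * (1 - max_missing):
            excluded += 1
            continue
        statuses = {g: str(s) for g, s in vals.items()}
        uniq = set(statuses.values())
        if uniq == {"A"}:
            pan = "conservative_A"
        elif uniq == {"B"}:
            pan = "conservative_B"
        else:
            pan = "variable"
        region = (regions[i] if regions is not None
                  else Interval("region", i, i + 1))
        calls.append(CompartmentCall(region, statuses, pan))
    return calls, excluded


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def incorporation_rate(n_incorporated: int, n_total: int) -> float:
    """Percentage of features successfully incorporated into the pan set."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_incorporated <= n_total:
        raise ValueError("n_incorporated outside [0, n_total]")
    return 100.0 * n_incorporated / n_total


def category_counts(clusters: Sequence[PanCluster]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for cl in clusters:
        counts[cl.category] += 1
    return counts


def clusters_to_table(clusters: Sequence[PanCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        span = cl.backbone_span
        rows.append({
            "cluster_id": cl.cluster_id, "kind": cl.feature_kind,
            "chrom": span.chrom if span else "",
            "start": span.start if span else -1,
            "end": span.end if span else -1,
            "anchor2_start": cl.anchor2_span.start if cl.anchor2_span else -1,
            "anchor2_end": cl.anchor2_span.end if cl.anchor2_span else -1,
            "presence_count": cl.presence_count, "n_genomes": cl.n_genomes,
            "category": cl.category,
            "members": ";".join(sorted(cl.members)),
        })
    return pd.DataFrame(rows)
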