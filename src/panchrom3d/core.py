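"""Coordinate conventions, interval algebra and liftover.

All coordinates are 0-based, half-open ``[start, end)`` — BED convention.
Every other module builds on the types and operations defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeCoordinates",
    "Interval",
    "AnchoredPair",
    "LiftoverBlock",
    "LiftoverMap",
    "LiftoverResult",
    "PresenceMatrix",
    "overlap_length",
    "reciprocal_overlap_fraction",
    "merge_with_gap",
    "liftover",
    "coverage_fraction",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomeCoordinates:
    """A backbone coordinate system: chromosome name -> length in bp."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        if len(chrom_sizes) == 0:
            raise ValueError("chrom_sizes must not be empty")
        for name, length in chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeCoordinates({self.chrom_sizes})"


@dataclass
class Interval:
    """A half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    genome_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class AnchoredPair:
    """A chromatin loop: two anchor intervals plus a contact statistic.

    For intra-chromosomal pairs ``anchor1`` is ordered before ``anchor2``.
    """

    anchor1: Interval
    anchor2: Interval
    score: float = 0.0
    genome_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.anchor1.chrom == self.anchor2.chrom
            and self.anchor1.start > self.anchor2.start
        ):
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1


@dataclass(frozen=True)
class LiftoverBlock:
    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    @property
    def tgt_end(self) -> int:
        return self.tgt_start + self.length


class LiftoverMap:
    """Ordered equal-length aligned blocks translating source -> target coordinates.

    The block model is the chain-file abstraction: within a block the mapping is
    a constant shift; between blocks lie unaligned gaps (indels).
    """

    def __init__(self, blocks: Iterable[LiftoverBlock]):
        blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start))
        by_chrom: dict[str, list[LiftoverBlock]] = {}
        for b in blocks:
            if b.src_end <= b.src_start:
                raise ValueError("empty liftover block")
            lst = by_chrom.setdefault(b.src_chrom, [])
            if lst and b.src_start < lst[-1].src_end:
                raise ValueError("overlapping liftover blocks in source coordinates")
            lst.append(b)
        self._by_chrom = by_chrom
        # per-chromosome arrays for bisection
        self._starts = {c: np.array([b.src_start for b in bs]) for c, bs in by_chrom.items()}

    @property
    def blocks(self) -> list[LiftoverBlock]:
        return [b for bs in self._by_chrom.values() for b in bs]

    def invert(self) -> "LiftoverMap":
        return LiftoverMap(
            LiftoverBlock(b.tgt_chrom, b.tgt_start, b.tgt_end, b.src_chrom, b.src_start)
            for b in self.blocks
        )

    def _block_at(self, chrom: str, pos: int) -> LiftoverBlock | None:
        """Return the block containing source position ``pos`` (half-open)."""
        if chrom not in self._by_chrom:
            return None
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return None
        b = self._by_chrom[chrom][i]
        return b if pos < b.src_end else None

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        b = self._block_at(chrom, pos)
        if b is None:
            return None
        return b.tgt_chrom, b.tgt_start + (pos - b.src_start)


@dataclass
class LiftoverResult:
    """Outcome of lifting one interval; ``interval`` is None when unmapped."""

    interval: Interval | None
    reason: str = "mapped"

    @property
    def mapped(self) -> bool:
        return self.interval is not None


class PresenceMatrix:
    """Feature clusters x genomes boolean presence table."""

    def __init__(self, presence: np.ndarray, genome_ids: Sequence[str],
                 cluster_ids: Sequence[str] | None = None):
        presence = np.asarray(presence, dtype=bool)
        if presence.ndim != 2:
            raise ValueError("presence must be 2-D")
        if presence.shape[1] != len(genome_ids):
            raise ValueError("column count must equal number of genome ids")
        if len(set(genome_ids)) != len(genome_ids):
            raise ValueError("genome ids must be unique")
        if presence.shape[0] and not presence.any(axis=1).all():
            raise ValueError("every cluster must be present in at least one genome")
        self.presence = presence
        self.genome_ids = list(genome_ids)
        self.cluster_ids = (
            list(cluster_ids) if cluster_ids is not None
            else [f"cluster_{i}" for i in range(presence.shape[0])]
        )

    @property
    def n_genomes(self) -> int:
        return self.presence.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.presence.shape[0]

    def presence_counts(self) -> np.ndarray:
        return self.presence.sum(axis=1)


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def overlap_length(a: Interval, b: Interval) -> int:
    """Base pairs shared by two intervals; 0 across chromosomes or when disjoint."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap_fraction(a: Interval, b: Interval) -> float:
    """Overlap length divided by the length of the SHORTER interval.

    Symmetric in its arguments; a nested interval scores 1.0.
    """
    shorter = min(a.length, b.length)
    if shorter <= 0:
        raise ValueError("zero-length interval")
    return overlap_length(a, b) / shorter


def merge_with_gap(intervals: Sequence[Interval], max_gap: int) -> list[Interval]:
    """Merge intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    The merged interval is the envelope of its members; contributing members
    (and their genome ids) are retained in ``meta['members']`` /
    ``meta['genomes']``.  Input order is irrelevant; merging is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    out: list[Interval] = []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    cur_members = [ordered[0]]
    cur = ordered[0]
    cur_start, cur_end = cur.start, cur.end
    for iv in ordered[1:]:
        if iv.chrom == cur.chrom and iv.start - cur_end <= max_gap:
            cur_members.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            out.append(_envelope(cur.chrom, cur_start, cur_end, cur_members))
            cur = iv
            cur_members = [iv]
            cur_start, cur_end = iv.start, iv.end
    out.append(_envelope(cur.chrom, cur_start, cur_end, cur_members))
    return out


def _envelope(chrom: str, start: int, end: int, members: list[Interval]) -> Interval:
    genomes = sorted({m.genome_id for m in members if m.genome_id})
    return Interval(chrom, start, end,
                    meta={"members": list(members), "genomes": genomes})


def liftover(iv: Interval, lift_map: LiftoverMap) -> LiftoverResult:
    """Map an interval through a block map; endpoints in unaligned gaps fail.

    When both endpoints lie in one block the result preserves length.  When
    they lie in different blocks each endpoint is mapped independently and the
    envelope kept, provided both land on the same chromosome in consistent
    order; otherwise the interval is unmapped with a reason code.
    """
    start_hit = lift_map.map_position(iv.chrom, iv.start)
    # end is exclusive: map the last covered base, then add one
    end_hit = lift_map.map_position(iv.chrom, iv.end - 1)
    if start_hit is None and end_hit is None:
        if lift_map._block_at(iv.chrom, iv.start) is None and iv.chrom not in {
            b.src_chrom for b in lift_map.blocks
        }:
            return LiftoverResult(None, "chrom_absent")
        return LiftoverResult(None, "unaligned")
    if start_hit is None or end_hit is None:
        return LiftoverResult(None, "endpoint_unaligned")
    (c1, p1), (c2, p2) = start_hit, end_hit
    if c1 != c2:
        return LiftoverResult(None, "split_chromosome")
    if p2 < p1:
        return LiftoverResult(None, "inverted_order")
    mapped = replace(iv, chrom=c1, start=p1, end=p2 + 1)
    return LiftoverResult(mapped)


def coverage_fraction(target: Interval, features: Sequence[Interval]) -> float:
    """Fraction of ``target`` covered by the union of ``features``."""
    if target.length <= 0:
        raise ValueError("empty target")
    return covered_bp(target, features) / target.length


def covered_bp(target: Interval, features: Sequence[Interval]) -> int:
    """Base pairs of ``target`` covered by the union of ``features``."""
    clipped = sorted(
        (max(f.start, target.start), min(f.end, target.end))
        for f in features
        if f.chrom == target.chrom and f.start < target.end and f.end > target.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered
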