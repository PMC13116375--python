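"""Chromatin-architecture calling from binned contact matrices.

Insulation-score TAD boundary detection (diamond window, Li minimum
cross-entropy threshold on boundary prominence), TADs as inter-boundary
spans, A/B compartments from the first eigenvector of the observed/expected
correlation matrix, map-resolution estimation, LT-CRE identification,
E/G loop-anchor typing, TAD reorganization classes, and boundary activity
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import AnchoredPair, Interval, covered_bp, overlap_length

#: floor for the insulation ratio before the log2, as a fraction of the
#: chromosome-mean insulation; keeps zero-contact windows finite while
#: ranking them below every real window.
IS_RATIO_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError("contact matrix must be finite")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_interval(self, i: int) -> Interval:
        return Interval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)


@dataclass
class InsulationTrack:
    """Per-bin insulation: raw diamond means and log2 mean-normalized scores.

    Scores are defined only where the full window fits (``valid`` mask).
    """

    chrom: str
    bin_size: int
    window: int
    raw: np.ndarray
    normalized: np.ndarray
    valid: np.ndarray


@dataclass
class BoundaryCall:
    interval: Interval
    strength: float
    passes_threshold: bool


@dataclass
class LTCRE:
    """An ATAC peak >= 2 kb from every TSS that lies on a loop anchor."""

    interval: Interval
    supporting_anchors: list[Interval]
    distance_to_nearest_tss: int


# ---------------------------------------------------------------------------
# Insulation score
# ---------------------------------------------------------------------------

def insulation_score(cm: ContactMatrix, w: int) -> InsulationTrack:
    """Diamond insulation: IS(b) = mean of M[i, j] for i in [b-w, b-1],
    j in [b+1, b+w] (center bin excluded)."""
    if w < 1:
        raise ValueError("window must be >= 1 bin")
    m = cm.matrix
    n = m.shape[0]
    if n <= 2 * w:
        raise ValueError("matrix side must exceed 2*w")
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for b in range(w, n - w):
        raw[b] = m[b - w:b, b + 1:b + w + 1].mean()
        valid[b] = True
    mean_is = raw[valid].mean()
    if mean_is == 0:
        raise ValueError("all-zero matrix: insulation cannot be normalized")
    normalized = np.full(n, np.nan)
    ratio = np.maximum(raw[valid] / mean_is, IS_RATIO_FLOOR)
    normalized[valid] = np.log2(ratio)
    return InsulationTrack(cm.chrom, cm.bin_size, w, raw, normalized, valid)


# ---------------------------------------------------------------------------
# Li threshold
# ---------------------------------------------------------------------------

def li_threshold(values: Sequence[float], tol: float = 1e-8,
                 max_iter: int = 1000) -> float:
    """Li & Lee minimum cross-entropy threshold by the iterative update
    t <- (mu_below - mu_above) / (ln mu_below - ln mu_above).

    Zeros/negatives are shifted by a small epsilon before iterating and the
    threshold shifted back.  Constant input raises.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least two distinct values")
    shift = 0.0
    if v.min() <= 0:
        shift = float(np.finfo(float).eps - v.min())
        v = v + shift
    t = v.mean()
    for _ in range(max_iter):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        m0, m1 = below.mean(), above.mean()
        if m0 == m1:
            break
        t_new = (m0 - m1) / (np.log(m0) - np.log(m1))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t - shift)


# ---------------------------------------------------------------------------
# Boundaries and TADs
# ---------------------------------------------------------------------------

def call_boundaries(track: InsulationTrack,
                    threshold: float | None = None) -> list[BoundaryCall]:
    """Boundary candidates are local minima of the normalized insulation;
    strength is the topographic prominence of each minimum.  Calls whose
    strength reaches the Li threshold over all candidate strengths (or an
    explicit ``threshold``) are flagged as passing.  Contiguous minimum bins
    (plateaus) merge into a single interval."""
    score = track.normalized[track.valid]
    offset = int(np.flatnonzero(track.valid)[0]) if track.valid.any() else 0
    if score.size < 3:
        return []
    idx, props = find_peaks(-score, prominence=0, plateau_size=(1, None))
    if idx.size == 0:
        return []
    strengths = props["prominences"]
    if threshold is None:
        try:
            threshold = li_threshold(strengths)
        except ValueError:       # all candidate strengths identical
            threshold = float(strengths[0])
    calls = []
    for k in range(idx.size):
        left = int(props["left_edges"][k]) + offset
        right = int(props["right_edges"][k]) + offset
        iv = Interval(track.chrom, left * track.bin_size,
                      (right + 1) * track.bin_size)
        calls.append(BoundaryCall(iv, float(strengths[k]),
                                  bool(strengths[k] >= threshold)))
    return calls


def passing_boundaries(calls: Sequence[BoundaryCall]) -> list[BoundaryCall]:
    return [c for c in calls if c.passes_threshold]


def call_tads(boundaries: Sequence[BoundaryCall | Interval],
              chrom: str, chrom_length: int) -> list[Interval]:
    """TADs are the spans between adjacent boundaries; the chromosome-end
    spans are emitted too, flagged ``partial`` in meta.  k boundaries always
    yield k + 1 spans."""
    ivs = sorted((b.interval if isinstance(b, BoundaryCall) else b
                  for b in boundaries), key=lambda iv: iv.start)
    edges = [0] + [e for b in ivs for e in (b.start, b.end)] + [chrom_length]
    tads = []
    for k in range(0, len(edges), 2):
        s, e = edges[k], edges[k + 1]
        partial = k == 0 or k == len(edges) - 2
        if e > s:
            tads.append(Interval(chrom, s, e, meta={"partial": partial}))
        else:       # boundary abuts the chromosome end: keep the span count
            tads.append(Interval(chrom, s, s + 1, meta={"partial": True,
                                                        "degenerate": True}))
    return tads


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------

def call_compartments(
    cm: ContactMatrix,
    orientation_track: np.ndarray,
) -> tuple[list[tuple[Interval, str]], np.ndarray]:
    """A/B compartment calls from the first eigenvector of the
    observed/expected Pearson correlation matrix.

    Bins with zero marginal are masked out.  The eigenvector sign is oriented
    so its correlation with ``orientation_track`` (typically gene density) is
    positive; positive entries are A, negative (and exact zeros) are B;
    contiguous same-label bins merge into compartment intervals.  Returns the
    merged calls and the per-bin eigenvector (NaN at masked bins).
    """
    m = cm.matrix
    n = m.shape[0]
    track = np.asarray(orientation_track, dtype=float)
    if track.shape != (n,):
        raise ValueError("orientation_track must have one value per bin")
    keep = m.sum(axis=1) > 0
    if keep.sum() < 3:
        raise ValueError("too few informative bins")
    sub = m[np.ix_(keep, keep)]
    oe = _observed_over_expected(sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]
    finite_track = track[keep]
    if np.std(finite_track) > 0 and np.std(ev) > 0:
        if np.corrcoef(ev, finite_track)[0, 1] < 0:
            ev = -ev
    full_ev = np.full(n, np.nan)
    full_ev[keep] = ev
    labels = np.where(full_ev > 0, "A", "B")
    calls: list[tuple[Interval, str]] = []
    run_start = None
    run_label = None
    for i in range(n + 1):
        lab = labels[i] if i < n and keep[i] else None
        if lab != run_label:
            if run_label is not None:
                calls.append((Interval(cm.chrom, run_start * cm.bin_size,
                                       i * cm.bin_size), run_label))
            run_start, run_label = i, lab
    return calls, full_ev


def _observed_over_expected(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    oe = np.array(m, dtype=float)
    idx = np.arange(n)
    for d in range(n):
        diag = m[idx[:n - d], idx[:n - d] + d]
        mu = diag.mean()
        if mu > 0:
            oe[idx[:n - d], idx[:n - d] + d] = diag / mu
            if d:
                oe[idx[:n - d] + d, idx[:n - d]] = diag / mu
    return oe


# ---------------------------------------------------------------------------
# Map resolution
# ---------------------------------------------------------------------------

def estimate_map_resolution(
    matrices: Mapping[int, ContactMatrix],
    min_contacts: int = 1000,
    min_fraction: float = 0.80,
) -> tuple[int, bool]:
    """Smallest bin size at which >= 80% of bins hold >= 1000 contacts.

    Returns (bin size, qualified).  When no binning qualifies, the largest
    bin size is returned with ``qualified=False``.
    """
    if not matrices:
        raise ValueError("need at least one candidate binning")
    fractions = {}
    for bs, cm in matrices.items():
        totals = cm.matrix.sum(axis=1)
        fractions[bs] = (totals >= min_contacts).mean()
    qualifying = [bs for bs in sorted(fractions) if fractions[bs] >= min_fraction]
    if qualifying:
        return qualifying[0], True
    return max(fractions), False


# ---------------------------------------------------------------------------
# LT-CREs and loop annotation
# ---------------------------------------------------------------------------

def tss_of(gene: Interval) -> int:
    """TSS position of a gene interval (strand in ``meta['strand']``)."""
    return gene.start if gene.meta.get("strand", "+") == "+" else gene.end - 1


def upstream_window(gene: Interval, size: int = 2000) -> Interval:
    """The ``size``-bp window immediately upstream of the TSS, strand-aware."""
    tss = tss_of(gene)
    if gene.meta.get("strand", "+") == "+":
        return Interval(gene.chrom, max(0, tss - size), max(1, tss))
    return Interval(gene.chrom, tss + 1, tss + 1 + size)


def _edge_distance(iv: Interval, pos: int) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end
    return 0


def identify_ltcres(
    peaks: Sequence[Interval],
    anchors: Sequence[Interval],
    tss_positions: Sequence[tuple[str, int]],
    min_tss_distance: int = 2000,
) -> list[LTCRE]:
    """ATAC peaks at least ``min_tss_distance`` from every TSS (edge-to-point)
    and covered by at least one loop anchor."""
    out = []
    for peak in peaks:
        dists = [_edge_distance(peak, pos) for chrom, pos in tss_positions
                 if chrom == peak.chrom]
        nearest = min(dists) if dists else np.iinfo(np.int64).max
        if nearest < min_tss_distance:
            continue
        support = [a for a in anchors if overlap_length(peak, a) > 0]
        if not support:
            continue
        out.append(LTCRE(peak, support, int(nearest)))
    return out


def annotate_loops(
    loops: Sequence[AnchoredPair],
    ltcres: Sequence[LTCRE | Interval],
    genes: Sequence[Interval],
    upstream: int = 2000,
    strand_aware: bool = True,
) -> list[str]:
    """Loop types from anchor content: E (anchor overlaps an LT-CRE; takes
    precedence), else G (anchor overlaps the 2-kb window upstream of a TSS),
    else unlabeled.  Types are E-E, E-G, G-G or unannotated."""
    cre_ivs = [c.interval if isinstance(c, LTCRE) else c for c in ltcres]
    if strand_aware:
        windows = [upstream_window(g, upstream) for g in genes]
    else:
        windows = []
        for g in genes:
            tss = tss_of(g)
            windows.append(Interval(g.chrom, max(0, tss - upstream),
                                    tss + upstream + 1))

    def label(anchor: Interval) -> str | None:
        if any(overlap_length(anchor, c) > 0 for c in cre_ivs):
            return "E"
        if any(overlap_length(anchor, wdw) > 0 for wdw in windows):
            return "G"
        return None

    types = []
    for loop in loops:
        l1, l2 = label(loop.anchor1), label(loop.anchor2)
        if l1 is None or l2 is None:
            types.append("unannotated")
        else:
            types.append("-".join(sorted((l1, l2))))
    return types


# ---------------------------------------------------------------------------
# TAD reorganization
# ---------------------------------------------------------------------------

def classify_tad_reorganization(
    ref_tads: Sequence[Interval],
    query_tads: Sequence[Interval],
    stable_frac: float = 0.8,
    fusion_each: float = 0.2,
    fusion_joint: float = 0.8,
    neo_max: float = 0.5,
) -> list[str]:
    """Per-query label: stable (one ref TAD reciprocally covering >= 80%),
    fusion (>= 2 refs each >= 20% of the query, jointly >= 80%), neo (refs
    cover <= 50% of the query), else unclassified."""
    labels = []
    for q in query_tads:
        overlaps = [(r, overlap_length(q, r)) for r in ref_tads
                    if overlap_length(q, r) > 0]
        union_cov = covered_bp(q, [r for r, _ in overlaps]) / q.length
        reciprocal = [
            (r, o) for r, o in overlaps
            if o / q.length >= stable_frac and o / r.length >= stable_frac
        ]
        big = [o for _, o in overlaps if o / q.length >= fusion_each]
        if len(reciprocal) == 1:
            labels.append("stable")
        elif len(big) >= 2 and sum(big) / q.length >= fusion_joint:
            labels.append("fusion")
        elif union_cov <= neo_max:
            labels.append("neo")
        else:
            labels.append("unclassified")
    return labels


# ---------------------------------------------------------------------------
# Boundary activity classes
# ---------------------------------------------------------------------------

ACTIVITY_CLASSES = ("active", "neutral", "inactive")


def cluster_boundary_activity(features: np.ndarray, seed: int = 0,
                              n_init: int = 50) -> np.ndarray:
    """K-means (k=3) on z-scored (ATAC, expression, gene count) features;
    clusters relabeled active/neutral/inactive by descending mean ATAC z."""
    from sklearn.cluster import KMeans

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("features must be (n_boundaries, 3)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 boundaries")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=3, n_init=n_init, random_state=seed).fit(z)
    order = np.argsort(-np.array([
        z[km.labels_ == k, 0].mean() for k in range(3)]))
    relabel = {int(order[i]): ACTIVITY_CLASSES[i] for i in range(3)}
    return np.array([relabel[int(l)] for l in km.labels_])


def classify_boundary_activity(
    boundaries: Sequence[Interval],
    atac_peaks: Sequence[Interval],
    expression: Mapping[str, float],
    genes: Sequence[Interval],
    flank: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-boundary activity class from ATAC coverage, mean expression of
    overlapping genes and gene count, measured in boundary +/- ``flank``."""
    feats = np.zeros((len(boundaries), 3))
    for i, b in enumerate(boundaries):
        region = Interval(b.chrom, max(0, b.start - flank), b.end + flank)
        feats[i, 0] = covered_bp(region, list(atac_peaks))
        hit = [g for g in genes if overlap_length(region, g) > 0]
        feats[i, 2] = len(hit)
        vals = [expression.get(g.meta.get("gene_id", ""), 0.0) for g in hit]
        feats[i, 1] = float(np.mean(vals)) if vals else 0.0
    return cluster_boundary_activity(feats, seed=seed)
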