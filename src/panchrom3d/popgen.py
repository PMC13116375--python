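"""Selection statistics and interval-coverage enrichment.

Weir & Cockerham (1984) variance-component Fst, per-site/windowed nucleotide
diversity, Fst x Pi-ratio candidate screening (top-5% joint rule, Euclidean
ranking), a length-preserving bootstrap null for SV coverage of chromatin
features, SV-loop gene linkage and pan-category enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnchoredPair, GenomeCoordinates, Interval, covered_bp, overlap_length
from .chromatin import upstream_window

FST_REPORT_RANGE = (-0.05, 1.0)


# ---------------------------------------------------------------------------
# Bootstrap coverage test
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    observed: float
    null_draws: np.ndarray
    p_depletion: float
    p_enrichment: float
    z_score: float
    n_draws: int
    seed: int | None


class _CoverageIndex:
    """Prefix-summed union of feature intervals for O(log n) coverage queries."""

    def __init__(self, features: Sequence[Interval]):
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._per_chrom[chrom] = (starts, ends, cum)

    def _cum_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Covered bp in [0, x) for each x."""
        if chrom not in self._per_chrom:
            return np.zeros_like(x)
        starts, ends, cum = self._per_chrom[chrom]
        i = np.searchsorted(starts, x, side="right")
        res = cum[i].astype(np.int64)
        inside = i > 0
        res[inside] -= np.maximum(0, ends[i[inside] - 1] - x[inside])
        return res

    def covered(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self._cum_at(chrom, ends) - self._cum_at(chrom, starts)


def bootstrap_coverage_test(
    features: Sequence[Interval],
    regions: Sequence[Interval],
    genome: GenomeCoordinates,
    n_draws: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Observed vs bootstrap-null coverage of ``regions`` by ``features``.

    Each null draw relocates every region to a uniform random start on a
    chromosome sampled proportional to length (among chromosomes long enough
    to hold it); features stay fixed; relocated regions may overlap.
    Coverage is summed covered bp over regions divided by summed region
    length.  Empirical p-values use the add-one convention (k+1)/(N+1).
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if n_draws < 100:
        raise ValueError("need at least 100 null draws")
    rng = np.random.default_rng(seed)
    index = _CoverageIndex(features)
    chroms = genome.chroms
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    total_len = sum(r.length for r in regions)
    observed_bp = sum(
        int(index.covered(r.chrom, np.array([r.start]), np.array([r.end]))[0])
        for r in regions)
    observed = observed_bp / total_len

    null_bp = np.zeros(n_draws, dtype=np.int64)
    for r in regions:
        eligible = lengths >= r.length
        if not eligible.any():
            raise ValueError(
                f"region of length {r.length} exceeds every chromosome")
        p = np.where(eligible, lengths, 0).astype(float)
        p /= p.sum()
        ci = rng.choice(len(chroms), size=n_draws, p=p)
        u = rng.random(n_draws)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if not sel.any():
                continue
            starts = (u[sel] * (lengths[k] - r.length)).astype(np.int64)
            null_bp[sel] += index.covered(chrom, starts, starts + r.length)
    null = null_bp / total_len
    p_dep = (int((null <= observed).sum()) + 1) / (n_draws + 1)
    p_enr = (int((null >= observed).sum()) + 1) / (n_draws + 1)
    sd = null.std()
    z = float((observed - null.mean()) / sd) if sd > 0 else 0.0
    return BootstrapResult(observed, null, p_dep, p_enr, z, n_draws, seed)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def wc_fst(gt_pop1: np.ndarray, gt_pop2: np.ndarray) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) theta-hat per biallelic site, plus the
    multi-site "weighted" Fst sum(a) / sum(a+b+c).

    Inputs are dosage matrices (n_sites x n_individuals), 0/1/2 with -1
    missing.  Sites monomorphic across both populations, or with fewer than
    2 non-missing individuals in either population, are NaN (excluded from
    the weighted estimate).
    """
    g1 = np.atleast_2d(np.asarray(gt_pop1))
    g2 = np.atleast_2d(np.asarray(gt_pop2))
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("populations must cover the same sites")
    a, b, c = _wc_components(g1, g2)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    ok = np.isfinite(a) & np.isfinite(denom) & (denom != 0)
    weighted = float(a[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
    return theta, weighted


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Per-site WC-84 variance components (a, b, c) for r = 2 populations."""
    stats1 = _pop_site_stats(g1)
    stats2 = _pop_site_stats(g2)
    n1, p1, h1 = stats1
    n2, p2, h2 = stats2
    valid = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    poly = (pbar > 0) & (pbar < 1)
    keep = valid & poly
    nanify = ~keep
    for arr in (a, b, c):
        arr[nanify] = np.nan
    return a, b, c


def _pop_site_stats(g: np.ndarray):
    missing = g < 0
    n = (~missing).sum(axis=1).astype(float)
    alt = np.where(missing, 0, g).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, np.where(missing, 0, g == 1).sum(axis=1) / n, np.nan)
    return n, p, h


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(
    gt: np.ndarray,
    positions: np.ndarray | None = None,
    window: int = 50_000,
    step: int = 25_000,
    seq_length: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Per-site pi = 2p(1-p) * n/(n-1) over n non-missing haplotypes, plus
    sliding-window pi (sum of site pi / window length) when positions are
    given."""
    g = np.atleast_2d(np.asarray(gt))
    missing = g < 0
    n_hap = 2 * (~missing).sum(axis=1).astype(np.int64)
    alt = np.where(missing, 0, g).sum(axis=1).astype(np.int64)
    # pi = (differing haplotype pairs) / (all pairs); the integer-count form
    # alt*(n-alt) / C(n,2) keeps it exact and equals 2p(1-p) n/(n-1)
    pairs = n_hap * (n_hap - 1) // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(n_hap >= 2,
                           (alt * (n_hap - alt)) / np.maximum(pairs, 1),
                           np.nan)
    if positions is None:
        return site_pi, None
    positions = np.asarray(positions, dtype=np.int64)
    order = np.argsort(positions)
    pos_sorted = positions[order]
    pi_sorted = np.nan_to_num(site_pi[order])
    cum = np.concatenate([[0.0], np.cumsum(pi_sorted)])
    end = seq_length if seq_length is not None else int(pos_sorted[-1]) + 1
    starts = np.arange(0, max(end - window, 0) + 1, step, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([0], dtype=np.int64)
    ends = starts + window
    lo = np.searchsorted(pos_sorted, starts, side="left")
    hi = np.searchsorted(pos_sorted, ends, side="left")
    win_pi = (cum[hi] - cum[lo]) / window
    table = pd.DataFrame({"start": starts, "end": ends,
                          "n_sites": hi - lo, "pi": win_pi})
    return site_pi, table


# ---------------------------------------------------------------------------
# Candidate screening
# ---------------------------------------------------------------------------

def build_selection_table(fst: np.ndarray, pi_pop1: np.ndarray,
                          pi_pop2: np.ndarray,
                          sv_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-SV selection table with the Pi-ratio (pop1 / pop2) and Fst clipped
    to the report range [-0.05, 1]."""
    fst = np.asarray(fst, dtype=float)
    pi1 = np.asarray(pi_pop1, dtype=float)
    pi2 = np.asarray(pi_pop2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi2 > 0, pi1 / pi2, np.nan)
    return pd.DataFrame({
        "sv_id": sv_ids if sv_ids is not None
        else [f"sv_{i}" for i in range(fst.size)],
        "fst": np.clip(fst, *FST_REPORT_RANGE),
        "pi_pop1": pi1, "pi_pop2": pi2, "pi_ratio": ratio,
    })


def screen_candidate_svs(table: pd.DataFrame,
                         top_frac: float = 0.05) -> pd.DataFrame:
    """Joint top-5% Fst AND Pi-ratio screen with Euclidean ranking.

    Candidates satisfy fst >= its (1 - top_frac) quantile AND pi_ratio >= its
    (1 - top_frac) quantile (linear-interpolation quantiles, cutoff ties
    included).  The Euclidean distance combines min-max scaled fst with
    min-max scaled log2(pi_ratio); candidates are ranked descending.
    """
    df = table.copy()
    finite = np.isfinite(df["fst"]) & np.isfinite(df["pi_ratio"])
    if finite.sum() < 20:
        raise ValueError("need at least 20 SVs with finite fst and pi_ratio")
    fst = df.loc[finite, "fst"].to_numpy()
    ratio = df.loc[finite, "pi_ratio"].to_numpy()
    q_f = np.quantile(fst, 1 - top_frac)
    q_r = np.quantile(ratio, 1 - top_frac)
    df["fst_quantile"] = np.nan
    df["ratio_quantile"] = np.nan
    df.loc[finite, "fst_quantile"] = stats.rankdata(fst) / fst.size
    df.loc[finite, "ratio_quantile"] = stats.rankdata(ratio) / ratio.size
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(np.where(ratio > 0, ratio, np.nan))
    x = _minmax(fst)
    y = _minmax(log_ratio)
    df["euclid"] = np.nan
    df.loc[finite, "euclid"] = np.sqrt(x ** 2 + np.nan_to_num(y) ** 2)
    df["candidate"] = False
    df.loc[finite, "candidate"] = (fst >= q_f) & (ratio >= q_r)
    return df.sort_values(["candidate", "euclid"],
                          ascending=[False, False], kind="mergesort")


def _minmax(v: np.ndarray) -> np.ndarray:
    finite = np.isfinite(v)
    if not finite.any():
        return np.zeros_like(v)
    lo, hi = v[finite].min(), v[finite].max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# SV-loop genes
# ---------------------------------------------------------------------------

def sv_loop_genes(
    sv_intervals: Sequence[Interval],
    loops: Sequence[AnchoredPair],
    genes: Sequence[Interval],
    upstream: int = 2000,
) -> pd.DataFrame:
    """Link SVs to distal genes through loops.

    A loop with an anchor overlapped by an SV (>= 1 bp) is an SV-loop; genes
    assigned to the OPPOSITE anchor (gene body overlap, or anchor overlapping
    the 2-kb upstream window of the TSS) are its SV-loop genes.  An SV
    hitting both anchors emits both directions, flagged.
    """
    rows = []
    for li, loop in enumerate(loops):
        for sv in sv_intervals:
            hit1 = overlap_length(sv, loop.anchor1) > 0
            hit2 = overlap_length(sv, loop.anchor2) > 0
            if not (hit1 or hit2):
                continue
            both = hit1 and hit2
            for hit, distal in ((hit1, loop.anchor2), (hit2, loop.anchor1)):
                if not hit:
                    continue
                distal_genes = [
                    g.meta.get("gene_id", f"gene_{gi}")
                    for gi, g in enumerate(genes)
                    if overlap_length(g, distal) > 0
                    or overlap_length(upstream_window(g, upstream), distal) > 0
                ]
                rows.append((sv.meta.get("sv_id", ""), li,
                             ";".join(distal_genes), both))
    return pd.DataFrame(rows, columns=["sv_id", "loop_index",
                                       "distal_genes", "both_anchors"])


# ---------------------------------------------------------------------------
# Pan-category enrichment
# ---------------------------------------------------------------------------

def pan_type_enrichment(
    candidate_categories: Sequence[str],
    all_categories: Sequence[str],
) -> pd.DataFrame:
    """Per-category proportions among candidates vs all clusters, with a
    hypergeometric enrichment p-value per category."""
    if len(candidate_categories) == 0:
        raise ValueError("empty candidate set")
    all_counts = pd.Series(all_categories).value_counts()
    cand_counts = pd.Series(candidate_categories).value_counts()
    M = len(all_categories)
    n = len(candidate_categories)
    rows = []
    for cat in all_counts.index:
        K = int(all_counts[cat])
        k = int(cand_counts.get(cat, 0))
        p = stats.hypergeom.sf(k - 1, M, K, n)
        rows.append((cat, k / n, K / M, k, K, float(p)))
    return pd.DataFrame(rows, columns=[
        "category", "candidate_prop", "overall_prop",
        "candidate_count", "overall_count", "p_enrichment"])
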