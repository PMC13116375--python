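"""Reproducible evaluation experiments on synthetic data.

Each function runs one planted-truth experiment end to end — generate data,
run the method, score against truth — and returns plain numbers.  They back
both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import chromatin, pan, popgen, sv as sv_mod, synth
from .core import GenomeCoordinates, Interval

PAN_KINDS = ("gene_family", "boundary", "ltcre", "loop", "sv")


def pan_exactness(seed: int = 1, n_clusters: int = 1000,
                  n_genomes: int = 15) -> dict[str, float]:
    """Fraction of planted conservation classes recovered per feature kind.

    Study-scale conditions: 15 genomes, ``n_clusters`` clusters per kind,
    class probabilities 0.30/0.13/0.29/0.28, coordinate jitter below half of
    each merge tolerance.
    """
    cfg = synth.SimConfig(
        seed=seed, n_genomes=n_genomes,
        chrom_sizes={f"chr{i}": 40_000_000 for i in range(1, 6)},
        n_gene_families=n_clusters, n_boundaries=n_clusters,
        n_ltcres=n_clusters, n_loops=n_clusters, n_svs=n_clusters)
    ds = synth.simulate_pan_dataset(cfg)
    out: dict[str, float] = {}

    recovered = [pan.classify_pan_category(int(c), n_genomes)
                 for c in ds.families.presence_counts()]
    out["gene_family"] = _agreement(recovered, ds.truth.classes["gene_family"])

    lifted_b, _ = pan.lift_features(ds.boundaries, ds.maps)
    cl = pan.cluster_lifted_intervals(lifted_b, pan.DEFAULT_MAX_GAP["boundary"])
    out["boundary"] = _agreement([c.category for c in cl],
                                 ds.truth.classes["boundary"])

    lifted_c, _ = pan.lift_features(ds.ltcres, ds.maps)
    cl = pan.cluster_lifted_intervals(lifted_c, pan.DEFAULT_MAX_GAP["ltcre"])
    out["ltcre"] = _agreement([c.category for c in cl],
                              ds.truth.classes["ltcre"])

    lifted_l, _ = pan.lift_loops(ds.loops, ds.maps)
    cl = pan.cluster_loops(lifted_l)
    out["loop"] = _agreement([c.category for c in cl],
                             ds.truth.classes["loop"])

    merged = sv_mod.merge_svs(ds.svs)
    cl = pan.classify_pan_svs(merged, n_genomes)
    out["sv"] = _agreement([c.category for c in cl], ds.truth.classes["sv"])
    return out


def _agreement(recovered, planted) -> float:
    if len(recovered) != len(planted):
        return 0.0
    return float(np.mean([r == p for r, p in zip(recovered, planted)]))


def boundary_benchmark(n_seeds: int = 20, n_tads: int = 20,
                       bin_size: int = 40_000, within: float = 5.0,
                       between: float = 1.0, w: int = 2,
                       tol_bins: int = 1, base_seed: int = 0) -> dict[str, float]:
    """Boundary recall/precision vs planted TAD junctions, averaged over
    seeds, with a +/- ``tol_bins`` matching tolerance."""
    recalls, precisions = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        tads = synth.plant_tads("chr1", n_tads, bin_size, seed=seed)
        cm = synth.simulate_contact_matrix(tads, bin_size, within, between,
                                           noise="poisson", seed=seed)
        track = chromatin.insulation_score(cm, w)
        calls = chromatin.passing_boundaries(chromatin.call_boundaries(track))
        junctions = [t.end // bin_size for t in tads[:-1]]
        call_bins = [set(range(c.interval.start // bin_size,
                               c.interval.end // bin_size)) for c in calls]
        tp_r = sum(any(any(abs(b - j) <= tol_bins for b in cb)
                       for cb in call_bins) for j in junctions)
        tp_p = sum(any(any(abs(b - j) <= tol_bins for b in cb)
                       for j in junctions) for cb in call_bins)
        recalls.append(tp_r / len(junctions))
        precisions.append(tp_p / max(len(calls), 1))
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions)), "n_seeds": n_seeds}


def _bootstrap_regions(seed: int = 0) -> tuple[GenomeCoordinates, list[Interval]]:
    genome = GenomeCoordinates({"chr1": 50_000_000, "chr2": 50_000_000})
    rng = np.random.default_rng(seed)
    regions = [Interval(c, int(s), int(s) + 40_000)
               for c in ("chr1", "chr2")
               for s in rng.integers(0, 49_000_000, 25)]
    return genome, regions


def bootstrap_calibration(n_replicates: int = 200, n_draws: int = 500,
                          n_svs: int = 2000, alpha: float = 0.05,
                          base_seed: int = 0) -> float:
    """Type-I error of the depletion test under the no-depletion generator:
    fraction of replicates with p_depletion <= alpha."""
    genome, regions = _bootstrap_regions(base_seed)
    hits = 0
    for rep in range(n_replicates):
        svs = synth.simulate_sv_placement(genome, regions, n_svs, 1.0,
                                          seed=base_seed + 1000 + rep)
        res = popgen.bootstrap_coverage_test(svs, regions, genome,
                                             n_draws=n_draws,
                                             seed=base_seed + 5000 + rep)
        hits += res.p_depletion <= alpha
    return hits / n_replicates


def bootstrap_power(n_seeds: int = 50, n_draws: int = 500,
                    n_svs: int = 10_000, factor: float = 0.3,
                    alpha: float = 0.01, base_seed: int = 0) -> float:
    """Power against a planted depletion: fraction of seeds with
    p_depletion <= alpha."""
    genome, regions = _bootstrap_regions(base_seed)
    hits = 0
    for s in range(n_seeds):
        svs = synth.simulate_sv_placement(genome, regions, n_svs, factor,
                                          seed=base_seed + s)
        res = popgen.bootstrap_coverage_test(svs, regions, genome,
                                             n_draws=n_draws,
                                             seed=base_seed + 10_000 + s)
        hits += res.p_depletion <= alpha
    return hits / n_seeds


def candidate_screen_recovery(n_svs: int = 1000, n_outliers: int = 10,
                              seed: int = 1) -> float:
    """Fraction of planted selection outliers (+5 SD on both axes) recovered
    by the joint top-5% screen."""
    rng = np.random.default_rng(seed)
    fst = rng.normal(0.1, 0.05, n_svs).clip(0, 1)
    ratio = np.exp(rng.normal(0, 0.3, n_svs))
    fst[:n_outliers] += 5 * fst.std()
    ratio[:n_outliers] *= np.exp(5 * 0.3)
    table = popgen.build_selection_table(
        fst, ratio, np.ones(n_svs), [f"sv_{i}" for i in range(n_svs)])
    out = popgen.screen_candidate_svs(table)
    cand = set(out.loc[out["candidate"], "sv_id"])
    return len(cand & {f"sv_{i}" for i in range(n_outliers)}) / n_outliers
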