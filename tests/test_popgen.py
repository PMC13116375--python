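"""Fst / pi estimators, bootstrap coverage test, candidate screening."""

import numpy as np
import pandas as pd
import pytest

from panchrom3d.core import AnchoredPair, GenomeCoordinates, Interval
from panchrom3d.popgen import (
    bootstrap_coverage_test,
    build_selection_table,
    nucleotide_diversity,
    pan_type_enrichment,
    screen_candidate_svs,
    sv_loop_genes,
    wc_fst,
)
from panchrom3d.synth import simulate_sv_placement


# ---------------------------------------------------------------------------
# Independent oracle: literal transcription of the WC-84 two-population
# variance components, computed per site with explicit scalar loops.
# ---------------------------------------------------------------------------

def wc_fst_oracle_site(pop1, pop2):
    r = 2
    samples = []
    for pop in (pop1, pop2):
        obs = [g for g in pop if g >= 0]
        n_i = len(obs)
        p_i = sum(obs) / (2 * n_i)
        h_i = sum(1 for g in obs if g == 1) / n_i
        samples.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = samples
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return None
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                             - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a / (a + b + c)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        theta, weighted = wc_fst(np.zeros((1, 10), int), np.full((1, 10), 2))
        assert theta[0] == pytest.approx(1.0)
        assert weighted == pytest.approx(1.0)

    def test_identical_balanced_pops_nonpositive(self):
        g = np.array([[0, 1, 1, 2]])     # 1 AA, 2 Aa, 1 aa in each pop
        theta, _ = wc_fst(g, g)
        assert theta[0] <= 0

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        g1 = rng.integers(0, 3, (100, 14))
        g2 = rng.integers(0, 3, (100, 18))
        # sprinkle missing calls
        g1[rng.random(g1.shape) < 0.05] = -1
        g2[rng.random(g2.shape) < 0.05] = -1
        theta, _ = wc_fst(g1, g2)
        for i in range(100):
            expected = wc_fst_oracle_site(g1[i].tolist(), g2[i].tolist())
            if expected is None:
                assert np.isnan(theta[i])
            else:
                assert theta[i] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_sites_excluded(self):
        g = np.zeros((3, 6), int)
        g[1] = [0, 1, 2, 0, 1, 2]
        theta, _ = wc_fst(g, g)
        assert np.isnan(theta[0]) and np.isnan(theta[2])
        assert np.isfinite(theta[1])


class TestPi:
    def test_four_haplotypes_two_alt(self):
        # 6 pairs, 4 differing -> pi = 2/3
        pi, _ = nucleotide_diversity(np.array([[1, 1]]))
        assert pi[0] == pytest.approx(2 / 3)

    def test_monomorphic_zero(self):
        pi, _ = nucleotide_diversity(np.array([[0, 0, 0]]))
        assert pi[0] == 0.0

    def test_matches_exhaustive_pairwise_count(self):
        rng = np.random.default_rng(5)
        gt = rng.integers(0, 3, (30, 8))
        pi, _ = nucleotide_diversity(gt)
        for i in range(30):
            haps = []
            for g in gt[i]:
                haps += [1] * g + [0] * (2 - g)
            diffs = sum(1 for a in range(len(haps)) for b in range(a)
                        if haps[a] != haps[b])
            pairs = len(haps) * (len(haps) - 1) // 2
            assert pi[i] == pytest.approx(diffs / pairs)

    def test_windowed_pi(self):
        gt = np.array([[1, 1], [1, 1], [0, 2]])
        positions = np.array([10_000, 30_000, 70_000])
        _, table = nucleotide_diversity(gt, positions, window=50_000,
                                        step=25_000, seq_length=100_000)
        site = 2 / 3           # pi = 2p(1-p) * n/(n-1) with p=.5, n=4
        assert table.loc[0, "pi"] == pytest.approx(2 * site / 50_000)
        assert table.loc[0, "n_sites"] == 2


class TestBootstrap:
    genome = GenomeCoordinates({"chr1": 2_000_000, "chr2": 2_000_000})

    def test_add_one_p_value_convention(self):
        # features tile everything except the observed region's hole, so the
        # observed coverage is 0 while every null draw is positive
        features = [Interval("chr1", 0, 2_000_000),
                    Interval("chr2", 0, 1_990_000)]
        regions = [Interval("chr2", 1_990_000, 2_000_000)]
        res = bootstrap_coverage_test(features, regions, self.genome,
                                      n_draws=1000, seed=0)
        assert res.observed == 0.0
        assert res.p_depletion == pytest.approx(1 / 1001, abs=1e-6)

    def test_saturated_features_not_enriched(self):
        features = [Interval("chr1", 0, 2_000_000),
                    Interval("chr2", 0, 2_000_000)]
        regions = [Interval("chr1", 500_000, 600_000)]
        res = bootstrap_coverage_test(features, regions, self.genome,
                                      n_draws=200, seed=1)
        assert res.observed == 1.0
        assert res.p_enrichment == 1.0       # every null draw also covered

    def test_region_longer_than_genome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_coverage_test(
                [Interval("chr1", 0, 10)],
                [Interval("chr1", 0, 1_500_000)],
                GenomeCoordinates({"chr1": 1_000_000, "chrM": 16_000}),
                n_draws=100, seed=0)
        # a chromosome that can hold the region keeps sampling valid even
        # when another chromosome cannot
        res = bootstrap_coverage_test(
            [Interval("chr1", 0, 10)], [Interval("chr1", 0, 1_000_000)],
            GenomeCoordinates({"chr1": 2_000_000, "chrM": 16_000}),
            n_draws=100, seed=0)
        assert res.n_draws == 100

    def test_planted_depletion_detected(self):
        genome = GenomeCoordinates({"chr1": 50_000_000})
        regions = [Interval("chr1", s, s + 100_000)
                   for s in range(2_000_000, 42_000_000, 4_000_000)]
        svs = simulate_sv_placement(genome, regions, 10_000, 0.3, seed=1)
        res = bootstrap_coverage_test(svs, regions, genome, n_draws=1000,
                                      seed=1)
        assert res.p_depletion <= 0.01
        assert res.z_score < 0


class TestScreen:
    def table(self, n=1000, n_outliers=10, seed=1):
        rng = np.random.default_rng(seed)
        fst = rng.normal(0.1, 0.05, n).clip(0, 1)
        ratio = np.exp(rng.normal(0, 0.3, n))
        fst[:n_outliers] += 5 * fst.std()
        ratio[:n_outliers] *= np.exp(5 * 0.3)
        return build_selection_table(fst, ratio, np.ones(n),
                                     [f"sv_{i}" for i in range(n)])

    def test_planted_outliers_all_recovered(self):
        df = screen_candidate_svs(self.table())
        cand = set(df.loc[df["candidate"], "sv_id"])
        assert {f"sv_{i}" for i in range(10)} <= cand

    def test_max_on_both_axes_ranks_first(self):
        df = self.table()
        i_max = df["fst"].idxmax()
        df.loc[i_max, "pi_ratio"] = df["pi_ratio"].max() * 2
        df.loc[i_max, "fst"] = df["fst"].max() + 0.1
        out = screen_candidate_svs(df)
        assert out.iloc[0]["sv_id"] == df.loc[i_max, "sv_id"]

    def test_joint_rule_requires_both_tails(self):
        df = self.table(seed=3)
        out = screen_candidate_svs(df)
        q_f = np.quantile(out["fst"], 0.95)
        q_r = np.quantile(out["pi_ratio"], 0.95)
        high_fst_only = out[(out["fst"] >= q_f) & (out["pi_ratio"] < q_r)]
        assert not high_fst_only["candidate"].any()

    def test_candidate_count_bounded(self):
        out = screen_candidate_svs(self.table(seed=4))
        assert out["candidate"].sum() <= 0.05 * len(out) + 10

    def test_too_few_svs_rejected(self):
        with pytest.raises(ValueError):
            screen_candidate_svs(self.table(n=10))


class TestSvLoopGenes:
    def loop(self, a1, a2):
        return AnchoredPair(Interval("chr1", *a1), Interval("chr1", *a2))

    def gene(self, start, end, gid):
        return Interval("chr1", start, end,
                        meta={"gene_id": gid, "strand": "+"})

    def test_distal_gene_reported(self):
        sv = Interval("chr1", 9_000, 11_000, meta={"sv_id": "sv1"})
        loops = [self.loop((10_000, 20_000), (200_000, 210_000))]
        genes = [self.gene(205_000, 208_000, "gA")]
        table = sv_loop_genes([sv], loops, genes)
        assert table.loc[0, "distal_genes"] == "gA"
        assert not table.loc[0, "both_anchors"]

    def test_loop_without_distal_gene_still_listed(self):
        sv = Interval("chr1", 9_000, 11_000, meta={"sv_id": "sv1"})
        loops = [self.loop((10_000, 20_000), (200_000, 210_000))]
        table = sv_loop_genes([sv], loops, [])
        assert len(table) == 1 and table.loc[0, "distal_genes"] == ""

    def test_sv_inside_loop_span_but_outside_anchors_ignored(self):
        sv = Interval("chr1", 100_000, 101_000, meta={"sv_id": "sv1"})
        loops = [self.loop((10_000, 20_000), (200_000, 210_000))]
        assert sv_loop_genes([sv], loops, []).empty

    def test_sv_hitting_both_anchors_flagged(self):
        sv = Interval("chr1", 15_000, 205_000, meta={"sv_id": "sv1"})
        loops = [self.loop((10_000, 20_000), (200_000, 210_000))]
        table = sv_loop_genes([sv], loops, [])
        assert len(table) == 2 and table["both_anchors"].all()


class TestPanTypeEnrichment:
    def test_core_only_candidates(self):
        all_cats = ["core"] * 50 + ["dispensable"] * 50
        out = pan_type_enrichment(["core"] * 10, all_cats)
        core = out[out["category"] == "core"].iloc[0]
        assert core["candidate_prop"] == 1.0
        assert core["p_enrichment"] < 0.01

    def test_uniform_candidates_not_significant(self):
        rng = np.random.default_rng(0)
        cats = ["core", "softcore", "dispensable", "private"]
        all_cats = [cats[i % 4] for i in range(400)]
        signif = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cand = [all_cats[i] for i in rng.choice(400, 40, replace=False)]
            out = pan_type_enrichment(cand, all_cats)
            signif += (out["p_enrichment"] < 0.05).any()
        # under the null, per-run "any category significant" stays uncommon
        assert signif <= 35

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            pan_type_enrichment([], ["core"])
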