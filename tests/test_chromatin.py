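"""Insulation scores, boundary/TAD calling, compartments and annotation."""

import numpy as np
import pytest

from panchrom3d.core import AnchoredPair, Interval
from panchrom3d.chromatin import (
    ContactMatrix,
    annotate_loops,
    call_boundaries,
    call_compartments,
    call_tads,
    classify_boundary_activity,
    classify_tad_reorganization,
    cluster_boundary_activity,
    estimate_map_resolution,
    identify_ltcres,
    insulation_score,
    li_threshold,
    passing_boundaries,
)
from panchrom3d.synth import plant_tads, simulate_contact_matrix


def two_block_matrix(block=3, within=1.0, between=0.0, bin_size=100):
    n = 2 * block
    m = np.full((n, n), between)
    m[:block, :block] = within
    m[block:, block:] = within
    return ContactMatrix("chr1", bin_size, m)


def iv(start, end, chrom="chr1", **meta):
    return Interval(chrom, start, end, meta=meta)


class TestInsulation:
    def test_two_block_single_cell_windows(self):
        track = insulation_score(two_block_matrix(), w=1)
        assert np.allclose(track.raw[track.valid], [1, 0, 0, 1])

    def test_uniform_matrix_constant(self):
        cm = ContactMatrix("chr1", 100, np.ones((8, 8)))
        track = insulation_score(cm, w=2)
        vals = track.raw[track.valid]
        assert np.allclose(vals, vals[0])

    def test_matches_brute_force_window_means(self):
        rng = np.random.default_rng(0)
        raw = rng.poisson(3, (40, 40)).astype(float)
        m = np.triu(raw) + np.triu(raw, 1).T
        cm = ContactMatrix("chr1", 100, m)
        for w in (1, 2, 3):
            track = insulation_score(cm, w)
            for b in range(w, 40 - w):
                acc = [m[i, j] for i in range(b - w, b)
                       for j in range(b + 1, b + w + 1)]
                assert track.raw[b] == pytest.approx(np.mean(acc))

    def test_minima_at_planted_junctions(self):
        tads = plant_tads("chr1", 4, 100, size_bins=(10, 10), seed=0)
        cm = simulate_contact_matrix(tads, 100, 5, 1, noise="none")
        track = insulation_score(cm, w=2)
        score = np.where(track.valid, track.raw, np.inf)
        junctions = {t.end // 100 for t in tads[:-1]}
        # each junction bin is a local minimum of the raw insulation
        for j in junctions:
            assert score[j] <= score[j - 1] and score[j] <= score[j + 1]

    def test_all_zero_matrix_rejected(self):
        cm = ContactMatrix("chr1", 100, np.zeros((10, 10)))
        with pytest.raises(ValueError, match="all-zero"):
            insulation_score(cm, 2)


class TestLiThreshold:
    def test_separates_two_groups(self):
        t = li_threshold([1, 1, 1, 9, 9, 9])
        assert 1 < t < 9

    def test_bimodal_sample(self):
        rng = np.random.default_rng(42)
        v = np.concatenate([rng.normal(1, 0.1, 100), rng.normal(10, 0.1, 100)])
        assert 2 < li_threshold(v) < 9

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(2, 0.2, 50), rng.normal(8, 0.2, 50)])
        assert li_threshold(2 * v) == pytest.approx(2 * li_threshold(v),
                                                    rel=1e-6)

    def test_agrees_with_reference_implementation(self):
        # scikit-image normalizes by shifting the minimum to zero first;
        # apply the same shift for a like-for-like comparison
        from skimage.filters import threshold_li

        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(1, 0.3, 200), rng.normal(12, 0.5, 200)])
        ours = li_threshold(v - v.min()) + v.min()
        assert ours == pytest.approx(threshold_li(v), rel=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            li_threshold([5, 5, 5])


class TestBoundaries:
    def test_two_block_fixture_single_merged_boundary(self):
        track = insulation_score(two_block_matrix(), w=1)
        calls = call_boundaries(track)
        assert len(calls) == 1
        # minimum plateau bins {2, 3} merge into [200, 400)
        assert (calls[0].interval.start, calls[0].interval.end) == (200, 400)

    def test_monotone_track_has_no_boundaries(self):
        m = np.fromfunction(lambda i, j: 20 - np.abs(i - j), (12, 12))
        track = insulation_score(ContactMatrix("chr1", 100, m), w=2)
        assert call_boundaries(track) == []

    def test_noise_free_ten_tads_all_junctions_found(self):
        tads = plant_tads("chr1", 10, 100, size_bins=(8, 12), seed=5)
        cm = simulate_contact_matrix(tads, 100, 5, 1, noise="none")
        calls = call_boundaries(insulation_score(cm, w=2))
        junctions = {t.end // 100 for t in tads[:-1]}
        called_bins = set()
        for c in calls:
            called_bins.update(range(c.interval.start // 100,
                                     c.interval.end // 100))
        assert junctions <= called_bins
        assert len(calls) == 9

    def test_strength_nonnegative_and_flagged(self):
        tads = plant_tads("chr1", 6, 100, seed=2)
        cm = simulate_contact_matrix(tads, 100, 5, 1, seed=2)
        calls = call_boundaries(insulation_score(cm, w=2))
        assert all(c.strength >= 0 for c in calls)
        assert passing_boundaries(calls) == [c for c in calls
                                             if c.passes_threshold]


class TestTads:
    def test_interior_and_flagged_end_spans(self):
        bounds = [iv(80_000, 160_000), iv(400_000, 440_000)]
        tads = call_tads(bounds, "chr1", 1_000_000)
        spans = [(t.start, t.end, t.meta["partial"]) for t in tads]
        assert spans == [(0, 80_000, True), (160_000, 400_000, False),
                         (440_000, 1_000_000, True)]

    def test_no_boundaries_whole_chromosome_flagged(self):
        tads = call_tads([], "chr1", 500_000)
        assert len(tads) == 1 and tads[0].meta["partial"]

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_span_count_is_boundary_count_plus_one(self, k):
        bounds = [iv(100_000 * (i + 1), 100_000 * (i + 1) + 10_000)
                  for i in range(k)]
        assert len(call_tads(bounds, "chr1", 2_000_000)) == k + 1


class TestCompartments:
    def block_matrix(self):
        # two interaction groups: bins 0-4 and 5-9
        m = np.full((10, 10), 0.2)
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        return ContactMatrix("chr1", 100_000, m)

    def test_eigenvector_partitions_blocks(self):
        track = np.array([1.0] * 5 + [0.0] * 5)
        calls, ev = call_compartments(self.block_matrix(), track)
        assert [(c[0].start // 100_000, c[0].end // 100_000, c[1])
                for c in calls] == [(0, 5, "A"), (5, 10, "B")]

    def test_flipping_orientation_flips_labels(self):
        track = np.array([1.0] * 5 + [0.0] * 5)
        calls_fwd, _ = call_compartments(self.block_matrix(), track)
        calls_rev, _ = call_compartments(self.block_matrix(), -track)
        assert [c[1] for c in calls_fwd] == ["A", "B"]
        assert [c[1] for c in calls_rev] == ["B", "A"]

    def test_scale_invariant(self):
        track = np.array([1.0] * 5 + [0.0] * 5)
        calls1, _ = call_compartments(self.block_matrix(), track)
        scaled = ContactMatrix("chr1", 100_000, self.block_matrix().matrix * 7)
        calls2, _ = call_compartments(scaled, track)
        assert [(c[0].start, c[1]) for c in calls1] == \
               [(c[0].start, c[1]) for c in calls2]

    def test_zero_marginal_bins_masked(self):
        m = self.block_matrix().matrix.copy()
        m[3, :] = 0
        m[:, 3] = 0
        cm = ContactMatrix("chr1", 100_000, m)
        calls, ev = call_compartments(cm, np.ones(10))
        assert np.isnan(ev[3])
        covered = {b for c in calls
                   for b in range(c[0].start // 100_000, c[0].end // 100_000)}
        assert 3 not in covered


class TestMapResolution:
    def make(self, bin_size, fraction, n=10):
        # fraction of bins with marginal >= 1000
        m = np.zeros((n, n))
        k = int(round(fraction * n))
        for i in range(k):
            m[i, i] = 1500
        return ContactMatrix("chr1", bin_size, m)

    def test_smallest_qualifying_binning(self):
        res, ok = estimate_map_resolution({10_000: self.make(10_000, 0.7),
                                           20_000: self.make(20_000, 0.9)})
        assert (res, ok) == (20_000, True)

    def test_all_pass_returns_smallest(self):
        res, ok = estimate_map_resolution({10_000: self.make(10_000, 0.9),
                                           20_000: self.make(20_000, 1.0)})
        assert (res, ok) == (10_000, True)

    def test_exact_eighty_percent_qualifies(self):
        res, ok = estimate_map_resolution({40_000: self.make(40_000, 0.8)})
        assert (res, ok) == (40_000, True)

    def test_none_qualifying_warns(self):
        res, ok = estimate_map_resolution({10_000: self.make(10_000, 0.1),
                                           40_000: self.make(40_000, 0.5)})
        assert (res, ok) == (40_000, False)


class TestLtcreAndLoops:
    def test_qualifying_peak(self):
        cres = identify_ltcres([iv(5000, 5400)], [iv(4800, 5600)],
                               [("chr1", 9000)])
        assert len(cres) == 1 and cres[0].distance_to_nearest_tss == 3600

    def test_peak_too_close_to_tss_rejected(self):
        assert identify_ltcres([iv(5000, 5400)], [iv(4800, 5600)],
                               [("chr1", 6000)]) == []

    def test_peak_without_anchor_rejected(self):
        assert identify_ltcres([iv(5000, 5400)], [iv(9000, 9500)],
                               [("chr1", 50_000)]) == []

    def loop(self, a1, a2):
        return AnchoredPair(iv(*a1), iv(*a2))

    def test_eg_typing(self):
        gene = iv(20_000, 25_000, strand="+")
        cre = iv(5100, 5300)
        loops = [self.loop((5000, 5400), (18_500, 19_200))]
        # anchor2 overlaps [18000, 20000) upstream of the + strand TSS
        assert annotate_loops(loops, [cre], [gene]) == ["E-G"]

    def test_ee_and_unannotated(self):
        cre1, cre2 = iv(5100, 5300), iv(30_000, 30_200)
        loops = [self.loop((5000, 5400), (29_900, 30_400)),
                 self.loop((100_000, 101_000), (200_000, 201_000))]
        assert annotate_loops(loops, [cre1, cre2], []) == ["E-E", "unannotated"]

    def test_e_takes_precedence_over_g(self):
        gene = iv(5600, 9000, strand="+")   # upstream window [3600, 5600)
        cre = iv(5100, 5300)
        loops = [self.loop((5000, 5400), (5050, 5450))]
        assert annotate_loops(loops, [cre], [gene]) == ["E-E"]


class TestTadReorganization:
    def test_fusion_stable_neo(self):
        ref = [iv(0, 100_000), iv(100_000, 200_000)]
        assert classify_tad_reorganization(ref, [iv(0, 200_000)]) == ["fusion"]
        assert classify_tad_reorganization([iv(0, 100_000)],
                                           [iv(0, 98_000)]) == ["stable"]
        assert classify_tad_reorganization(ref,
                                           [iv(300_000, 400_000)]) == ["neo"]

    def test_unclassified_middle_ground(self):
        # one ref covering 70% of the query: not stable, fusion or neo
        labels = classify_tad_reorganization([iv(0, 70_000)], [iv(0, 100_000)])
        assert labels == ["unclassified"]


class TestBoundaryActivity:
    def separated_features(self, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        groups = []
        for mu in (10.0, 5.0, 0.0):
            groups.append(np.column_stack([
                rng.normal(mu, 0.1, n_per),
                rng.normal(mu, 0.1, n_per),
                rng.normal(mu, 0.1, n_per)]))
        return np.vstack(groups)

    def test_well_separated_groups_recovered_in_atac_order(self):
        x = self.separated_features()
        labels = cluster_boundary_activity(x, seed=0)
        assert (labels[:10] == "active").all()
        assert (labels[10:20] == "neutral").all()
        assert (labels[20:] == "inactive").all()

    def test_permutation_invariant(self):
        x = self.separated_features()
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(x))
        labels = cluster_boundary_activity(x, seed=0)
        permuted = cluster_boundary_activity(x[perm], seed=0)
        assert (permuted == labels[perm]).all()

    def test_duplication_invariant(self):
        x = self.separated_features()
        labels = cluster_boundary_activity(x, seed=0)
        doubled = cluster_boundary_activity(np.vstack([x, x]), seed=0)
        assert (doubled[:len(x)] == labels).all()

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValueError):
            cluster_boundary_activity(np.zeros((2, 3)))

    def test_feature_extraction_wrapper(self):
        bounds = [iv(100_000, 140_000), iv(500_000, 540_000),
                  iv(900_000, 940_000)]
        peaks = [iv(95_000, 130_000), iv(500_000, 510_000)]
        genes = [iv(110_000, 120_000, gene_id="g1", strand="+"),
                 iv(505_000, 512_000, gene_id="g2", strand="+")]
        labels = classify_boundary_activity(
            bounds, peaks, {"g1": 5.0, "g2": 1.0}, genes, seed=0)
        assert labels.shape == (3,)
        assert labels[0] == "active" and labels[2] == "inactive"
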