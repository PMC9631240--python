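import numpy as np
import pytest

import midasmap as mm
from midasmap.errors import InfeasibleSamplingError, ValidationError
from oracles import (
    genes_in_window_oracle,
    nearest_origin_oracle,
    overlap_pairs_oracle,
)


def site(chrom, anchor, sid="s", sigma=5.0):
    b = anchor // 10_000
    return mm.MidasSite(chrom, b * 10_000, (b + 1) * 10_000, [b], anchor, sigma,
                        "single", site_id=sid)


def random_sites(rng, n, chroms=("chr1", "chr2"), span=5_000_000):
    return [site(rng.choice(chroms), int(rng.integers(10_000, span)), f"s{i}")
            for i in range(n)]


def random_intervals(rng, n, kind, chroms=("chr1", "chr2"), span=5_000_000):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        ivs.append(mm.GenomicInterval(str(rng.choice(chroms)), start,
                                      start + int(rng.integers(500, 80_000)),
                                      "+", f"{kind}{i}"))
    return mm.IntervalSet(ivs, kind)


class TestOverlapSiteSets:
    def test_distance_arithmetic_at_the_window_edge(self):
        a = [site("chr1", 1_000_000)]
        assert mm.overlap_site_sets(a, [site("chr1", 1_550_000)])["n_a_matched"] == 1
        assert mm.overlap_site_sets(a, [site("chr1", 1_700_000)])["n_a_matched"] == 0
        assert mm.overlap_site_sets(a, [site("chr2", 1_000_000)])["n_a_matched"] == 0

    def test_identity_matches_every_site(self):
        rng = np.random.default_rng(0)
        a = random_sites(rng, 40)
        res = mm.overlap_site_sets(a, a)
        assert res["n_a_matched"] == len(a) == res["n_b_matched"]

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b = random_sites(rng, 30), random_sites(rng, 40)
            w = int(rng.integers(0, 800_000))
            res = mm.overlap_site_sets(a, b, w)
            want = overlap_pairs_oracle(a, b, w)
            assert sorted(res["pairs"]) == sorted(want)
            assert res["n_a_matched"] == len({i for i, _ in want})
            assert res["n_b_matched"] == len({j for _, j in want})


class TestReplicationTiming:
    def domains(self):
        return mm.IntervalSet(
            [mm.GenomicInterval("chr1", 0, 100_000, ".", "early"),
             mm.GenomicInterval("chr1", 100_000, 200_000, ".", "mid"),
             mm.GenomicInterval("chr1", 300_000, 400_000, ".", "late")],
            "rt_domain")

    def test_anchor_containment_and_gaps(self):
        labels = mm.assign_replication_timing(
            [site("chr1", 50_000), site("chr1", 250_000), site("chr1", 350_000)],
            self.domains())
        assert labels == ["early", "undefined", "late"]

    def test_region_straddling_boundary_uses_anchor(self):
        s = mm.MidasSite("chr1", 90_000, 110_000, [9], 95_000, 5.0, "single")
        assert mm.assign_replication_timing([s], self.domains()) == ["early"]

    def test_overlapping_domains_rejected(self):
        bad = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 0, 100_000, ".", "early"),
             mm.GenomicInterval("chr1", 50_000, 150_000, ".", "late")], "rt_domain")
        with pytest.raises(ValidationError):
            mm.assign_replication_timing([site("chr1", 10_000)], bad)


class TestGenicClassification:
    def test_window_edges(self):
        anchor = 500_000
        genes = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 440_000, 451_000, "+", "near_left"),
             mm.GenomicInterval("chr1", 551_000, 560_000, "+", "far_right")], "gene")
        df = mm.classify_genic([site("chr1", anchor)], genes)
        assert df.loc[0, "genic"] == "genic"
        assert df.loc[0, "genes_within_window"] == "near_left"

    def test_no_genes_means_intergenic(self):
        df = mm.classify_genic([site("chr1", 100_000)], mm.IntervalSet([], "gene"))
        assert df.loc[0, "genic"] == "intergenic"
        assert df.loc[0, "gene_count_window"] == 0

    def test_counts_match_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        sites = random_sites(rng, 100)
        genes = random_intervals(rng, 100, "gene")
        df = mm.classify_genic(sites, genes)
        dens = mm.gene_density(sites, genes)
        for row, s, c in zip(df.itertuples(), sites, dens["counts"]):
            want = genes_in_window_oracle(s, genes, 50_000)
            assert row.gene_count_window == len(want) == c
            assert (row.genic == "genic") == bool(want)


class TestNearestOrigin:
    def test_forced_examples(self):
        origins = mm.IntervalSet([mm.GenomicInterval("chr1", 100_000, 101_000)], "origin")
        (d,) = mm.nearest_origin_distance([site("chr1", 205_000)], origins)
        assert d == 99_000
        (d,) = mm.nearest_origin_distance([site("chr1", 100_500)], origins)
        assert d == 0
        origins = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 1_240_000, 1_241_000),
             mm.GenomicInterval("chr1", 2_110_000, 2_111_000)], "origin")
        (d,) = mm.nearest_origin_distance([site("chr1", 1_205_000)], origins)
        assert d == 30_000

    def test_unassigned_without_origin_on_chromosome(self):
        origins = mm.IntervalSet([mm.GenomicInterval("chr2", 0, 1_000)], "origin")
        assert mm.nearest_origin_distance([site("chr1", 50_000)], origins) == [None]

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(3)
        sites = random_sites(rng, 100)
        origins = random_intervals(rng, 60, "origin")
        got = mm.nearest_origin_distance(sites, origins)
        for s, d in zip(sites, got):
            assert d == nearest_origin_oracle(s, origins)


class TestCfsGenes:
    def test_disjoint_and_subset(self):
        assert mm.cfs_gene_overlap(["a", "b"], ["c"])["fraction"] == 0
        res = mm.cfs_gene_overlap(["a", "b"], ["A ", "b", "z"])
        assert res == {"n_hit": 2, "n_total": 2, "fraction": 1.0}

    def test_empty_site_genes_rejected(self):
        with pytest.raises(ValidationError):
            mm.cfs_gene_overlap([], ["a"])


class TestGeneSizes:
    def test_identical_sets_null_case(self):
        s = mm.IntervalSet([mm.GenomicInterval("chr1", 0, l) for l in (10, 20, 30)], "gene")
        res = mm.summarize_gene_sizes(s, s)
        assert res["median_site"] == res["median_ref"] == 20
        assert res["test_p"] > 0.05

    def test_shifted_lengths_detected(self):
        rng = np.random.default_rng(4)
        small = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 0, int(l)) for l in rng.integers(30_000, 60_000, 50)], "gene")
        big = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 0, int(l)) for l in rng.integers(400_000, 700_000, 50)], "gene")
        res = mm.summarize_gene_sizes(small, big)
        assert res["median_site"] < res["median_ref"]
        assert res["test_p"] < 1e-6


class TestControlSampling:
    def test_infeasible_pool_reports_size(self, default_world):
        cfg, truth, counts, _ = default_world
        sites = mm.call_midas_sites(mm.compute_sigma(counts))
        with pytest.raises(InfeasibleSamplingError) as err:
            mm.sample_control_regions(truth.rt_domains, truth.rloop_peaks, sites,
                                      truth.genes, truth.layout, n=10**6)
        assert err.value.pool_size < 10**6

    def test_same_seed_reproduces_identical_sets(self, default_world):
        cfg, truth, counts, _ = default_world
        sites = mm.call_midas_sites(mm.compute_sigma(counts))
        args = (truth.rt_domains, truth.rloop_peaks, sites, truth.genes, truth.layout)
        a = mm.sample_control_regions(*args, n=50, n_sets=3, seed=11)
        b = mm.sample_control_regions(*args, n=50, n_sets=3, seed=11)
        assert [cs.regions for cs in a] == [cs.regions for cs in b]
        c = mm.sample_control_regions(*args, n=50, n_sets=3, seed=12)
        assert [cs.regions for cs in a] != [cs.regions for cs in c]

    def test_every_region_passes_constraint_recheck(self, default_world):
        """Sampled regions are early-replicating, R-loop prone and off-MiDAS."""
        cfg, truth, counts, _ = default_world
        sites = mm.call_midas_sites(mm.compute_sigma(counts))
        sets = mm.sample_control_regions(truth.rt_domains, truth.rloop_peaks, sites,
                                         truth.genes, truth.layout, seed=5)
        early = [iv for iv in truth.rt_domains if iv.label == "early"]
        peak_bins = {}
        for s in sites:
            peak_bins.setdefault(s.chrom, set()).update(s.peak_bins)
        for cs in sets:
            assert len(cs.regions) == 150
            assert len(set((iv.chrom, iv.start) for iv in cs.regions)) == 150
            for iv in cs.regions:
                center = (iv.start + iv.end) // 2
                assert any(d.chrom == iv.chrom and d.start <= center < d.end for d in early)
                b = center // 10_000
                assert not any(abs(b - p) <= 50 for p in peak_bins.get(iv.chrom, ()))
                assert truth.rloop_peaks.count_overlapping(
                    iv.chrom, center - 50_000, center + 50_000) >= 1
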