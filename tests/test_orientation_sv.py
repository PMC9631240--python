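import numpy as np
import pytest

import midasmap as mm
from midasmap.errors import NoDataError, ValidationError
from oracles import sv_frequency_oracle
from test_annotation import random_sites, site


def rfd_track(vec, bin_size=10_000, chrom="chr1"):
    layout = mm.GenomeLayout((chrom,), (len(vec) * bin_size,), bin_size)
    return mm.RFDTrack(layout, {chrom: np.asarray(vec, float)})


class TestMeanRFD:
    def test_constant_track(self):
        assert mm.mean_rfd_over_site(site("chr1", 500_000), rfd_track([0.6] * 200)) == pytest.approx(0.6)

    def test_balanced_values_cancel(self):
        vec = np.zeros(200)
        vec[42:50] = 1.0
        vec[50:58] = -1.0
        # window of 150 kb centered on bin 50's midpoint covers bins 42..57
        assert mm.mean_rfd_over_site(site("chr1", 505_000), rfd_track(vec), window=160_000) == 0.0

    def test_random_window_equals_direct_mean(self):
        rng = np.random.default_rng(0)
        vec = rng.uniform(-1, 1, 300)
        s = site("chr1", 1_505_000)
        got = mm.mean_rfd_over_site(s, rfd_track(vec), window=150_000)
        lo, hi = (s.anchor - 75_000) // 10_000, (s.anchor + 75_000) // 10_000
        assert got == pytest.approx(vec[lo:hi].mean())

    def test_all_missing_raises(self):
        with pytest.raises(NoDataError):
            mm.mean_rfd_over_site(site("chr1", 500_000), rfd_track([np.nan] * 200))

    def test_missing_bins_excluded_not_zeroed(self):
        vec = np.full(200, np.nan)
        vec[49] = 0.8
        assert mm.mean_rfd_over_site(site("chr1", 505_000), rfd_track(vec)) == pytest.approx(0.8)


class TestOrientationCalls:
    @pytest.mark.parametrize("strand,rfd,call", [
        ("+", 0.8, "co-directional"),
        ("+", -0.8, "head-on"),
        ("-", -0.8, "co-directional"),
        ("-", 0.8, "head-on"),
        ("+", 0.05, "ambiguous"),
        ("-", -0.05, "ambiguous"),
    ])
    def test_sign_and_threshold_rules(self, strand, rfd, call):
        assert mm.classify_orientation(site("chr1", 0o000 + 5_000), strand, rfd).call == call

    def test_summary_fractions(self):
        calls = [mm.classify_orientation(site("chr1", 5_000), "+", r)
                 for r in (0.5, 0.7, -0.5, 0.01)]
        summ = mm.orientation_summary(calls)
        assert summ["fraction_codirectional"] == 0.5
        assert summ["fraction_headon"] == 0.25
        assert summ["fraction_ambiguous"] == 0.25
        assert summ["fraction_codirectional"] + summ["fraction_headon"] + summ["fraction_ambiguous"] == 1.0

    def test_empty_calls_rejected(self):
        with pytest.raises(ValidationError):
            mm.orientation_summary([])

    def test_negating_the_track_swaps_co_and_head_on(self, default_world):
        """Orientation calls are antisymmetric in the sign of the RFD track."""
        cfg, truth, counts, _ = default_world
        called = mm.call_midas_sites(mm.compute_sigma(counts))
        fwd, _ = mm.classify_sites_orientation(called, truth.genes, truth.rfd)
        rev, _ = mm.classify_sites_orientation(called, truth.genes, truth.rfd.negated())
        swap = {"co-directional": "head-on", "head-on": "co-directional",
                "ambiguous": "ambiguous"}
        assert len(fwd) == len(rev) > 0
        for f, r in zip(fwd, rev):
            assert r.call == swap[f.call]
            assert r.mean_rfd == pytest.approx(-f.mean_rfd)

    def test_multi_gene_sites_are_skipped_not_failed(self):
        genes = mm.IntervalSet(
            [mm.GenomicInterval("chr1", 480_000, 520_000, "+", "a"),
             mm.GenomicInterval("chr1", 530_000, 540_000, "-", "b")], "gene")
        calls, skipped = mm.classify_sites_orientation(
            [site("chr1", 505_000)], genes, rfd_track([0.5] * 200))
        assert calls == [] and skipped == 1


def catalog_3_tumors():
    records = [
        mm.SVRecord("t1", "BRCA2-mutated", "chr1", 1_150_000, "chr1", 1_160_000, "DEL"),
        mm.SVRecord("t2", "BRCA2-mutated", "chr1", 1_250_000, "chr1", 1_260_000, "DEL"),
        mm.SVRecord("t3", "BRCA2-mutated", "chr2", 1_150_000, "chr2", 1_160_000, "DEL"),
    ]
    return mm.SVCatalog(records, {"t1": "BRCA2-mutated", "t2": "BRCA2-mutated", "t3": "BRCA2-mutated"})


class TestSVFrequency:
    def test_empty_catalog_gives_zero_everywhere(self):
        cat = mm.SVCatalog([], {"t1": "BRCA2-mutated", "t2": "BRCA2-wild-type"})
        freq = mm.site_sv_frequency([site("chr1", 1_005_000)], cat)
        assert freq.loc[0, "pct_BRCA2-mutated"] == 0.0
        assert freq.loc[0, "pct_BRCA2-wild-type"] == 0.0

    def test_three_tumor_window_example(self):
        """One in-window breakpoint out of three tumors -> 33.3%."""
        freq = mm.site_sv_frequency([site("chr1", 1_005_000)], catalog_3_tumors())
        assert freq.loc[0, "pct_BRCA2-mutated"] == pytest.approx(100 / 3)

    def test_tumor_with_two_breakpoints_counts_once(self):
        cat = catalog_3_tumors()
        cat.records.append(
            mm.SVRecord("t1", "BRCA2-mutated", "chr1", 1_100_000, "chr1", 1_120_000, "DEL"))
        freq = mm.site_sv_frequency([site("chr1", 1_005_000)], cat)
        assert freq.loc[0, "pct_BRCA2-mutated"] == pytest.approx(100 / 3)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        cohorts = {}
        records = []
        for t in range(40):
            sid = f"t{t}"
            cohorts[sid] = "BRCA2-mutated" if t % 3 == 0 else "BRCA2-wild-type"
            for _ in range(int(rng.integers(0, 6))):
                c1, c2 = rng.choice(["chr1", "chr2"], 2)
                records.append(mm.SVRecord(sid, cohorts[sid], str(c1),
                                           int(rng.integers(0, 5_000_000)), str(c2),
                                           int(rng.integers(0, 5_000_000)), "TRA"))
        cat = mm.SVCatalog(records, cohorts)
        sites = random_sites(rng, 30)
        freq = mm.site_sv_frequency(sites, cat, 200_000)
        for row, s in zip(freq.to_dict("records"), sites):
            want = sv_frequency_oracle(s, records, cohorts, 200_000)
            assert row["pct_BRCA2-mutated"] == pytest.approx(want.get("BRCA2-mutated", 0))
            assert row["pct_BRCA2-wild-type"] == pytest.approx(want.get("BRCA2-wild-type", 0))

    def test_percentages_bounded_and_monotone_in_window(self):
        rng = np.random.default_rng(2)
        cohorts = {f"t{t}": "BRCA2-mutated" for t in range(20)}
        records = [mm.SVRecord(f"t{t}", "BRCA2-mutated", "chr1",
                               int(rng.integers(0, 5_000_000)), "chr1",
                               int(rng.integers(0, 5_000_000)), "DEL") for t in range(20)]
        cat = mm.SVCatalog(records, cohorts)
        sites = random_sites(rng, 20, chroms=("chr1",))
        prev = None
        for w in (50_000, 200_000, 600_000):
            freq = mm.site_sv_frequency(sites, cat, w)["pct_BRCA2-mutated"].to_numpy()
            assert np.all((0 <= freq) & (freq <= 100))
            if prev is not None:
                assert np.all(freq >= prev)
            prev = freq


class TestCohortComparison:
    def test_identical_groups_not_significant(self):
        g = np.array([5.0, 6.0, 5.5, 4.5] * 5)
        res = mm.cohort_sv_comparison({"a": g, "b": g})
        assert res["tukey"][0]["p_adj"] > 0.5

    def test_shifted_group_significant(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5, 1, 100)
        res = mm.cohort_sv_comparison({"wt": base, "mut": base + 10})
        assert res["anova_p"] < 1e-10
        assert res["tukey"][0]["p_adj"] < 0.01

    def test_group_means_match_direct_computation(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 30, 20), rng.uniform(0, 30, 20)
        res = mm.cohort_sv_comparison({"a": a, "b": b})
        assert res["group_means"]["a"] == pytest.approx(a.mean())
        assert res["group_medians"]["b"] == pytest.approx(np.median(b))

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            mm.cohort_sv_comparison({"a": [1.0], "b": [1.0, 2.0]})


def test_sv_table_round_trip(tmp_path, default_world):
    cfg, truth, counts, catalog = default_world
    p = tmp_path / "svs.tsv"
    mm.write_sv_table(catalog, p)
    back = mm.read_sv_table(p)
    assert back.cohorts == catalog.cohorts
    assert back.records == catalog.records
    assert back.samples_per_cohort == {
        "BRCA2-wild-type": cfg.n_tumors_wildtype,
        "BRCA2-mutated": cfg.n_tumors_mutated,
    }
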