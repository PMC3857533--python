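from __future__ import annotations

import numpy as np
import pytest

from circtraits import (
    AgoSite,
    GenomicInterval,
    IntervalIndex,
    SNPRecord,
    density_statistics,
    gene_overlap_count,
    gwas_trait_breakdown,
    map_intervals_to_loci,
    map_points_to_loci,
    snps_in_ago_sites_within_circrnas,
)

from conftest import random_loci, random_snps
from oracles import naive_interval_hits, naive_point_hits, naive_snps_in_ago_in_circ


def snp(rsid, chrom, pos0, trait=""):
    return SNPRecord(rsid, chrom, pos0, trait)


class TestPointMapping:
    @pytest.mark.parametrize(
        "pos0,expected", [(99, 0), (100, 1), (150, 1), (199, 1), (200, 0)]
    )
    def test_half_open_boundaries(self, pos0, expected):
        loci = [("circA", GenomicInterval("chr1", 100, 200, "+"))]
        report = map_points_to_loci([snp("rs1", "chr1", pos0)], loci)
        assert report.mapping_count == expected

    def test_empty_inputs_give_zero_counts(self, toy_loci):
        report = map_points_to_loci([], toy_loci)
        assert report.mapping_count == report.unique_feature_count == 0
        assert report.mean_per_mapped_locus == 0.0

    def test_overlapping_loci_count_with_multiplicity(self, toy_loci):
        report = map_points_to_loci([snp("rs1", "chr1", 175)], toy_loci)
        assert report.unique_feature_count == 1
        assert report.mapping_count == 2
        assert {h[1] for h in report.hits} == {"circA", "circB"}

    def test_strand_is_ignored_for_points(self, toy_loci):
        # circB is minus-strand; the point still hits it
        report = map_points_to_loci([snp("rs1", "chr1", 300)], toy_loci)
        assert report.hits == [("rs1", "circB", None)]


class TestIntervalMapping:
    def test_identical_intervals_hit_same_strand_only(self):
        iv = GenomicInterval("chr1", 100, 200, "+")
        site_same = AgoSite("s+", iv)
        site_opp = AgoSite("s-", GenomicInterval("chr1", 100, 200, "-"))
        loci = [("c1", iv)]
        assert map_intervals_to_loci([site_same], loci, True).mapping_count == 1
        assert map_intervals_to_loci([site_opp], loci, True).mapping_count == 0
        assert map_intervals_to_loci([site_opp], loci, False).mapping_count == 1

    def test_single_bp_overlap_counts(self):
        loci = [("c1", GenomicInterval("chr1", 100, 200, "+"))]
        site = AgoSite("s1", GenomicInterval("chr1", 199, 250, "+"))
        report = map_intervals_to_loci([site], loci, True)
        assert report.hits == [("s1", "c1", 1)]

    def test_touching_intervals_do_not_overlap(self):
        loci = [("c1", GenomicInterval("chr1", 100, 200, "+"))]
        site = AgoSite("s1", GenomicInterval("chr1", 200, 250, "+"))
        assert map_intervals_to_loci([site], loci, True).mapping_count == 0


class TestSnpsInAgoSites:
    def test_toy_counts(self):
        loci = [("c1", GenomicInterval("chr1", 0, 1000, "+"))]
        sites = [
            AgoSite("a1", GenomicInterval("chr1", 100, 130, "+")),
            AgoSite("a2", GenomicInterval("chr1", 500, 540, "+")),
        ]
        snps = [snp(f"rs{i}", "chr1", p) for i, p in enumerate([110, 120, 520, 900])]
        report = snps_in_ago_sites_within_circrnas(snps, sites, loci)
        assert report.per_circ_counts == {"c1": 3}
        assert report.circrnas_with_snp_in_site == 1
        assert report.mean_count_over_hit_circrnas == 3.0

    def test_snp_outside_sites_or_outside_circ_not_counted(self):
        loci = [("c1", GenomicInterval("chr1", 0, 100, "+"))]
        sites = [AgoSite("a1", GenomicInterval("chr1", 500, 540, "+"))]
        snps = [snp("in_circ", "chr1", 50), snp("in_site", "chr1", 510)]
        report = snps_in_ago_sites_within_circrnas(snps, sites, loci)
        assert report.per_circ_counts == {"c1": 0}

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            loci = random_loci(rng, int(rng.integers(1, 30)), span=20_000)
            snps = random_snps(rng, int(rng.integers(0, 200)), span=20_000)
            sites = [
                AgoSite(f"a{i}", iv)
                for i, (_, iv) in enumerate(random_loci(rng, 20, span=20_000))
            ]
            got = snps_in_ago_sites_within_circrnas(snps, sites, loci)
            assert got.per_circ_counts == naive_snps_in_ago_in_circ(snps, sites, loci)


class TestDensityStatistics:
    def test_hand_checked_arithmetic(self):
        loci = [
            ("c1", GenomicInterval("chr1", 0, 1000, "+")),
            ("c2", GenomicInterval("chr1", 5000, 8000, "+")),
        ]
        snps = [snp(f"rs{i}", "chr1", p) for i, p in enumerate(
            [10, 20, 30, 40, 50, 5100, 5200, 5300, 5400, 5500]
        )]
        report = map_points_to_loci(snps, loci)
        mean_all, aggregate, mean_dens = density_statistics(report, loci)
        assert mean_all == 5.0
        assert aggregate == pytest.approx(10 / 4.0)
        assert mean_dens == pytest.approx((5 / 1.0 + 5 / 3.0) / 2)

    def test_zero_mappings_give_zero_statistics(self, toy_loci):
        report = map_points_to_loci([], toy_loci)
        assert density_statistics(report, toy_loci) == (0.0, 0.0, 0.0)

    def test_single_locus_densities_coincide(self):
        loci = [("c1", GenomicInterval("chr1", 0, 2000, "+"))]
        report = map_points_to_loci([snp("rs1", "chr1", 5)], loci)
        _, aggregate, mean_dens = density_statistics(report, loci)
        assert aggregate == pytest.approx(mean_dens)

    def test_empty_loci_rejected(self, toy_loci):
        report = map_points_to_loci([], toy_loci)
        with pytest.raises(ValueError):
            density_statistics(report, [])


class TestTraitBreakdown:
    def test_multiplicity_mean_and_per_trait_sets(self, toy_loci):
        # one trait SNP inside the chr1 overlap region hits two circRNAs
        snps = [snp("rs1", "chr1", 175, "height"), snp("rs2", "chr9", 5, "height")]
        b = gwas_trait_breakdown(snps, toy_loci)
        assert b.circrnas_by_trait == {"height": {"circA", "circB"}}
        assert b.unique_snp_count == 1
        assert b.mapped_circrna_count == 2
        assert b.mean_snps_per_mapped_circrna == 1.0

    def test_unlabelled_snps_excluded(self, toy_loci):
        b = gwas_trait_breakdown([snp("rs1", "chr1", 175, "")], toy_loci)
        assert b.circrnas_by_trait == {} and b.unique_snp_count == 0


def test_gene_overlap_count_is_intersection_size():
    assert gene_overlap_count({"A", "B", "C"}, {"B", "C", "D"}) == 2
    assert gene_overlap_count({"A"}, {"B"}) == 0
    assert gene_overlap_count({"A", "B"}, {"A", "B"}) == 2


class TestOracleEquivalence:
    """The indexed implementations must agree exactly with naive all-pairs
    scans, including at boundary positions, and be order-independent."""

    def test_point_and_interval_mapping_match_naive(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            loci = random_loci(rng, int(rng.integers(1, 100)))
            snps = random_snps(rng, int(rng.integers(0, 300)))
            # force all four boundary positions of some loci
            for locus_id, iv in loci[:20]:
                for pos in (iv.start - 1, iv.start, iv.end - 1, iv.end):
                    if pos >= 0:
                        snps.append(snp(f"rsb{locus_id}_{pos}", iv.chrom, pos))
            got = map_points_to_loci(snps, loci)
            assert [(r, l) for r, l, _ in got.hits] == naive_point_hits(snps, loci)
            sites = [
                AgoSite(f"a{i}", iv)
                for i, (_, iv) in enumerate(random_loci(rng, int(rng.integers(1, 80))))
            ]
            for aware in (True, False):
                got = map_intervals_to_loci(sites, loci, aware)
                assert got.hits == naive_interval_hits(sites, loci, aware)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        loci = random_loci(rng, 50)
        snps = random_snps(rng, 200)
        base = map_points_to_loci(snps, loci)
        perm = rng.permutation(len(snps))
        shuffled = map_points_to_loci([snps[i] for i in perm], loci)
        assert base == shuffled

    def test_conservation_identities(self):
        rng = np.random.default_rng(17)
        loci = random_loci(rng, 60)
        snps = random_snps(rng, 500)
        report = map_points_to_loci(snps, loci)
        assert report.mapping_count == sum(report.per_locus_hits.values())
        assert report.unique_feature_count <= report.mapping_count
        if report.mapped_locus_count:
            assert report.mean_per_mapped_locus * report.mapped_locus_count == (
                pytest.approx(report.mapping_count)
            )


def test_interval_index_rejects_duplicate_ids():
    iv = GenomicInterval("chr1", 0, 10, "+")
    with pytest.raises(ValueError, match="unique"):
        IntervalIndex([("a", iv), ("a", iv)])
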