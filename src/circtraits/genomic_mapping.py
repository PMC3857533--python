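"""Interval mapping of variants and Ago binding sites into circRNA loci.

Maps genome-wide SNPs, trait-associated (GWAS) SNPs and Ago PAR-CLIP
binding sites into circRNA loci, treating each circRNA as the linear
genomic span between its backsplice coordinates. All coordinates are
0-based half-open; a point hits a locus iff start <= pos0 < end, and two
intervals overlap iff they share >= 1 bp (max of starts < min of ends).

Point (SNP) mapping ignores strand; interval (Ago-site) mapping is
strand-aware by default since PAR-CLIP clusters and circRNAs are both
stranded — both behaviours are flag-controlled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .data_io import AgoSite, GenomicInterval, MappingReport, SNPRecord

logger = logging.getLogger(__name__)


class IntervalIndex:
    """Per-chromosome searchable index over (id, GenomicInterval) records.

    Backed by an interval tree per chromosome; strand filtering is applied
    on the query result. Queries return exactly what a naive all-pairs
    scan returns.
    """

    def __init__(self, records: Iterable[tuple[str, GenomicInterval]]) -> None:
        records = list(records)
        ids = [rid for rid, _ in records]
        if len(ids) != len(set(ids)):
            raise ValueError("record ids must be unique")
        self.records = records
        self._trees: dict[str, IntervalTree] = {}
        for rid, iv in records:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (rid, iv)
            )

    def query_point(self, chrom: str, pos0: int) -> list[tuple[str, GenomicInterval]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((node.data for node in tree.at(pos0)), key=lambda r: r[0])

    def query_interval(
        self, query: GenomicInterval, strand_aware: bool = False
    ) -> list[tuple[str, GenomicInterval]]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        out = [
            node.data
            for node in tree.overlap(query.start, query.end)
            if not strand_aware or node.data[1].strand == query.strand
        ]
        return sorted(out, key=lambda r: r[0])


def map_points_to_loci(
    snps: Sequence[SNPRecord],
    loci: Sequence[tuple[str, GenomicInterval]],
) -> MappingReport:
    """Map point variants into loci (strand ignored for points).

    A SNP hits a locus iff same chromosome and locus.start <= pos0 <
    locus.end. Every (rsid, locus_id) pair is recorded; mapping_count
    counts multiplicity across overlapping loci.
    """
    index = IntervalIndex(loci)
    hits: list[tuple[str, str, int | None]] = []
    for snp in snps:
        for locus_id, _ in index.query_point(snp.chrom, snp.pos0):
            hits.append((snp.rsid, locus_id, None))
    return MappingReport.from_hits(hits, loci)


def map_intervals_to_loci(
    sites: Sequence[AgoSite],
    loci: Sequence[tuple[str, GenomicInterval]],
    strand_aware: bool = True,
) -> MappingReport:
    """Map interval features (Ago binding sites) into loci.

    A site hits a locus iff same chromosome, >= 1 bp overlap, and — when
    strand_aware — equal strands. Hits carry the overlap length in bp.
    """
    index = IntervalIndex(loci)
    hits: list[tuple[str, str, int | None]] = []
    for site in sites:
        for locus_id, locus_iv in index.query_interval(site.locus, strand_aware):
            hits.append((site.site_id, locus_id, site.locus.overlap_bp(locus_iv)))
    return MappingReport.from_hits(hits, loci)


@dataclass
class AgoSNPReport:
    """SNP counts inside Ago binding sites intersected with circRNA loci."""

    per_circ_counts: dict[str, int]  # every circRNA, zero-hit included
    circrnas_with_snp_in_site: int
    mean_count_over_hit_circrnas: float


def snps_in_ago_sites_within_circrnas(
    snps: Sequence[SNPRecord],
    sites: Sequence[AgoSite],
    loci: Sequence[tuple[str, GenomicInterval]],
    strand_aware: bool = True,
) -> AgoSNPReport:
    """Count, per circRNA, the SNPs falling inside the intersection of an
    Ago site and the circRNA's locus.

    A SNP inside the circRNA but outside every Ago site, or inside an Ago
    site that does not overlap the circRNA, is not counted. A SNP covered
    by several Ago sites within one circRNA counts once for that circRNA.
    """
    site_index = IntervalIndex([(s.site_id, s.locus) for s in sites])
    locus_index = IntervalIndex(loci)
    counted: set[tuple[str, str]] = set()  # (rsid, locus_id)
    for snp in snps:
        in_sites = site_index.query_point(snp.chrom, snp.pos0)
        if not in_sites:
            continue
        for locus_id, locus_iv in locus_index.query_point(snp.chrom, snp.pos0):
            for _, site_iv in in_sites:
                if strand_aware and site_iv.strand != locus_iv.strand:
                    continue
                # SNP lies in both already; intersection is non-empty here
                counted.add((snp.rsid, locus_id))
                break
    per_circ = {locus_id: 0 for locus_id, _ in loci}
    for _, locus_id in counted:
        per_circ[locus_id] += 1
    hit = [n for n in per_circ.values() if n > 0]
    return AgoSNPReport(
        per_circ_counts=per_circ,
        circrnas_with_snp_in_site=len(hit),
        mean_count_over_hit_circrnas=sum(hit) / len(hit) if hit else 0.0,
    )


def density_statistics(
    report: MappingReport,
    loci: Sequence[tuple[str, GenomicInterval]],
) -> tuple[float, float, float]:
    """(mean_per_locus_all, aggregate_density_per_kb, mean_of_per_locus_densities).

    mean_per_locus_all averages mapping counts over *all* loci, zero-hit
    included. Two density readings are reported because "variants per kb"
    admits both an aggregate (total hits / total length) and a mean of
    per-locus densities; they differ when hit rates vary with locus length.
    """
    if not loci:
        raise ValueError("loci must be non-empty")
    total_kb = sum(iv.length() for _, iv in loci) / 1000.0
    if total_kb == 0:
        raise ValueError("zero total locus length")
    mean_all = report.mapping_count / len(loci)
    aggregate = report.mapping_count / total_kb
    per_locus = [
        report.per_locus_hits.get(locus_id, 0) / (iv.length() / 1000.0)
        for locus_id, iv in loci
    ]
    return mean_all, aggregate, sum(per_locus) / len(per_locus)


@dataclass
class TraitBreakdown:
    """Per-trait circRNA hits for GWAS/trait-associated SNPs."""

    circrnas_by_trait: dict[str, set[str]]
    unique_snp_count: int
    mapped_circrna_count: int
    mean_snps_per_mapped_circrna: float  # counts mappings with multiplicity


def gwas_trait_breakdown(
    snps: Sequence[SNPRecord],
    loci: Sequence[tuple[str, GenomicInterval]],
) -> TraitBreakdown:
    """Map trait-labelled SNPs into loci and break hits down by trait.

    SNPs with an empty trait label are excluded. The per-circRNA mean
    counts mappings with multiplicity: a SNP inside two circRNAs
    contributes two mapping events.
    """
    trait_snps = [s for s in snps if s.trait]
    report = map_points_to_loci(trait_snps, loci)
    trait_of = {s.rsid: s.trait for s in trait_snps}
    by_trait: dict[str, set[str]] = {}
    for rsid, locus_id, _ in report.hits:
        by_trait.setdefault(trait_of[rsid], set()).add(locus_id)
    return TraitBreakdown(
        circrnas_by_trait=by_trait,
        unique_snp_count=report.unique_feature_count,
        mapped_circrna_count=report.mapped_locus_count,
        mean_snps_per_mapped_circrna=report.mean_per_mapped_locus,
    )


def gene_overlap_count(network_genes: set[str], known_genes: set[str]) -> int:
    """Size of the overlap between network genes and a known disease-gene
    list (same identifier namespace assumed)."""
    return len(set(network_genes) & set(known_genes))


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_hits_tsv(report: MappingReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tlocus_id\toverlap_bp\n")
        for feature_id, locus_id, overlap in report.hits:
            fh.write(f"{feature_id}\t{locus_id}\t{'' if overlap is None else overlap}\n")


def write_per_locus_tsv(report: MappingReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("locus_id\tn_hits\tlength_bp\tdensity_per_kb\n")
        for locus_id in sorted(report.per_locus_hits):
            n = report.per_locus_hits[locus_id]
            length = report.locus_lengths[locus_id]
            fh.write(f"{locus_id}\t{n}\t{length}\t{n / (length / 1000.0):.6f}\n")


def summary_dict(report: MappingReport) -> dict:
    return {
        "unique_feature_count": report.unique_feature_count,
        "mapped_locus_count": report.mapped_locus_count,
        "mapping_count": report.mapping_count,
        "mean_per_mapped_locus": report.mean_per_mapped_locus,
        "mean_per_locus_all": report.mean_per_locus_all,
        "aggregate_density_per_kb": report.aggregate_density_per_kb,
    }


def write_summary_json(sections: dict[str, dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sections, fh, indent=2, sort_keys=True)
        fh.write("\n")
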