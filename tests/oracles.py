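"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the hypergeometric tail, and naive all-pairs scans for the
interval mappings.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_tail_p(M_T: int, m_c: int, M_d: int, m_d: int) -> Fraction:
    """Exact upper-tail hypergeometric probability as a rational number."""
    num = sum(
        comb(M_d, i) * comb(M_T - M_d, m_c - i)
        for i in range(m_d, min(m_c, M_d) + 1)
    )
    return Fraction(num, comb(M_T, m_c))


def naive_point_hits(snps, loci):
    """All (rsid, locus_id) pairs by scanning every SNP against every locus."""
    hits = []
    for snp in snps:
        for locus_id, iv in loci:
            if iv.chrom == snp.chrom and iv.start <= snp.pos0 < iv.end:
                hits.append((snp.rsid, locus_id))
    return sorted(hits)


def naive_interval_hits(sites, loci, strand_aware):
    """All (site_id, locus_id, overlap_bp) triples by an all-pairs scan."""
    hits = []
    for site in sites:
        siv = site.locus
        for locus_id, iv in loci:
            if iv.chrom != siv.chrom:
                continue
            if strand_aware and iv.strand != siv.strand:
                continue
            overlap = min(iv.end, siv.end) - max(iv.start, siv.start)
            if overlap >= 1:
                hits.append((site.site_id, locus_id, overlap))
    return sorted(hits)


def naive_snps_in_ago_in_circ(snps, sites, loci, strand_aware=True):
    """Per-circRNA count of SNPs inside (Ago site ∩ circRNA locus)."""
    counts = {locus_id: 0 for locus_id, _ in loci}
    for locus_id, liv in loci:
        seen = set()
        for snp in snps:
            if not (liv.chrom == snp.chrom and liv.start <= snp.pos0 < liv.end):
                continue
            for site in sites:
                siv = site.locus
                if siv.chrom != snp.chrom or not siv.start <= snp.pos0 < siv.end:
                    continue
                if strand_aware and siv.strand != liv.strand:
                    continue
                seen.add(snp.rsid)
                break
        counts[locus_id] = len(seen)
    return counts
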