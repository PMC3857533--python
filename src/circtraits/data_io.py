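"""Domain types and readers/writers for the pipeline's external formats.

Coordinate convention
---------------------
All internal coordinates are 0-based half-open ``[start, end)``, i.e. the
native BED convention. 1-based inputs (dbSNP / GWAS-catalog style TSVs) are
converted exactly once, at read time, via the ``coordinate_convention``
argument of :func:`read_snps`. Genome-build agreement between the circRNA
loci and the variant catalogs is the caller's responsibility.

Formats
-------
* BED6 for circRNA loci and Ago binding sites (``.`` in column 6 means
  unstranded).
* TSV (tab-separated, header row, UTF-8, ``#`` comment lines ignored) for
  interaction tables, disease-miRNA maps, SNP catalogs and gene lists.
* All writers emit LF line endings; p-values are written with 12+
  significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TARGET_CLASSES = ("circRNA", "mRNA", "lncRNA")

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span in 0-based half-open coordinates.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def overlap_bp(self, other: "GenomicInterval", strand_aware: bool = False) -> int:
        """Length of the shared span in bp; 0 when disjoint or filtered out."""
        if self.chrom != other.chrom:
            return 0
        if strand_aware and self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CircRNA:
    circ_id: str
    locus: GenomicInterval
    annotation: str = ""


@dataclass(frozen=True)
class SNPRecord:
    """A catalog variant. Empty ``trait`` means genome-wide catalog only;
    any non-empty string marks it as a GWAS/trait-associated SNP."""

    rsid: str
    chrom: str
    pos0: int
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos0 < 0:
            raise ValueError(f"negative position for {self.rsid}: {self.pos0}")


@dataclass(frozen=True)
class AgoSite:
    site_id: str
    locus: GenomicInterval


class InteractionTable:
    """Bipartite miRNA -> target edges with a target class.

    ``edges`` is a frozenset of ``(mirna_id, target_id, target_class)``
    triples; ``mirna_universe`` holds every miRNA considered (its size is
    M_T in the enrichment test). The universe always contains the edge
    miRNAs; an explicit, larger universe may be supplied to pin M_T to an
    external catalog size.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        mirna_universe: Iterable[str] | None = None,
    ) -> None:
        self.edges = frozenset(edges)
        for mirna, target, cls in self.edges:
            if cls not in TARGET_CLASSES:
                raise ValueError(
                    f"unknown target_class {cls!r} on edge ({mirna}, {target})"
                )
        observed = {e[0] for e in self.edges}
        if mirna_universe is None:
            self.mirna_universe = frozenset(observed)
        else:
            self.mirna_universe = frozenset(mirna_universe)
            missing = observed - self.mirna_universe
            if missing:
                raise ValueError(
                    f"{len(missing)} edge miRNAs absent from the supplied "
                    f"universe, e.g. {sorted(missing)[:3]}"
                )
        self._by_target: dict[tuple[str, str], set[str]] | None = None

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionTable)
            and self.edges == other.edges
            and self.mirna_universe == other.mirna_universe
        )

    def _target_map(self) -> dict[tuple[str, str], set[str]]:
        if self._by_target is None:
            m: dict[tuple[str, str], set[str]] = {}
            for mirna, target, cls in self.edges:
                m.setdefault((target, cls), set()).add(mirna)
            self._by_target = m
        return self._by_target

    def mirnas_of_target(self, target_id: str, target_class: str) -> frozenset[str]:
        return frozenset(self._target_map().get((target_id, target_class), ()))

    def targets_of(self, mirna_id: str) -> frozenset[tuple[str, str]]:
        return frozenset(
            (t, c) for m, t, c in self.edges if m == mirna_id
        )

    def target_ids(self, target_class: str) -> frozenset[str]:
        return frozenset(
            t for (t, c) in self._target_map() if c == target_class
        )


@dataclass
class DiseaseMiRNAMap:
    """disease name -> set of associated miRNA ids (the M_d sets).

    ``curated_subset``, when present for a disease, restricts to entries
    with a defined and validated role; it must be a subset of the full set.
    """

    map: dict[str, frozenset[str]]
    curated_subset: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.map = {d: frozenset(s) for d, s in self.map.items()}
        self.curated_subset = {d: frozenset(s) for d, s in self.curated_subset.items()}
        for d, s in self.map.items():
            if not s:
                raise ValueError(f"disease {d!r} has an empty miRNA set")
        for d, s in self.curated_subset.items():
            if d not in self.map or not s <= self.map[d]:
                raise ValueError(
                    f"curated subset for {d!r} is not a subset of its full set"
                )

    def diseases(self) -> list[str]:
        return sorted(self.map)

    def mirnas(self, disease: str, curated_only: bool = False) -> frozenset[str] | None:
        """The disease's miRNA set; None when curated_only is requested but
        no curated subset exists for the disease."""
        if disease not in self.map:
            raise KeyError(f"unknown disease {disease!r}")
        if curated_only:
            return self.curated_subset.get(disease)
        return self.map[disease]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (circRNA, disease) hypergeometric test.

    M_T: universe size; m_c: miRNAs hitting the circRNA; M_d: miRNAs of the
    disease (within the universe); m_d: disease miRNAs hitting the circRNA;
    m: circRNAs tested for this disease (Bonferroni family size).
    """

    circ_id: str
    disease: str
    M_T: int
    m_c: int
    M_d: int
    m_d: int
    p: float
    m: int
    p_threshold: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.m_d <= min(self.m_c, self.M_d) and self.M_d <= self.M_T
                and self.m_c <= self.M_T):
            raise ValueError(
                f"inconsistent counts for ({self.circ_id}, {self.disease}): "
                f"M_T={self.M_T} m_c={self.m_c} M_d={self.M_d} m_d={self.m_d}"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")
        if self.significant != (self.p < self.p_threshold):
            raise ValueError("significance flag inconsistent with p vs threshold")


@dataclass
class MappingReport:
    """Hits of point or interval features against a set of loci, plus the
    aggregate statistics reported alongside.

    ``hits`` holds ``(feature_id, locus_id, overlap_bp)`` tuples
    (``overlap_bp`` is None for point features). ``per_locus_hits`` has an
    entry for every locus, including zero-hit ones. ``mapping_count``
    counts multiplicity: a feature in two overlapping loci contributes two.
    """

    hits: list[tuple[str, str, int | None]]
    per_locus_hits: dict[str, int]
    locus_lengths: dict[str, int]
    unique_feature_count: int
    mapped_locus_count: int
    mapping_count: int
    mean_per_mapped_locus: float
    mean_per_locus_all: float
    aggregate_density_per_kb: float

    @classmethod
    def from_hits(
        cls,
        hits: Iterable[tuple[str, str, int | None]],
        loci: Sequence[tuple[str, GenomicInterval]],
    ) -> "MappingReport":
        hits = sorted(hits, key=lambda h: (h[0], h[1]))
        per_locus = {locus_id: 0 for locus_id, _ in loci}
        for _, locus_id, _ in hits:
            per_locus[locus_id] += 1
        lengths = {locus_id: iv.length() for locus_id, iv in loci}
        mapping_count = len(hits)
        mapped = sum(1 for n in per_locus.values() if n > 0)
        total_kb = sum(lengths.values()) / 1000.0
        return cls(
            hits=hits,
            per_locus_hits=per_locus,
            locus_lengths=lengths,
            unique_feature_count=len({h[0] for h in hits}),
            mapped_locus_count=mapped,
            mapping_count=mapping_count,
            mean_per_mapped_locus=mapping_count / mapped if mapped else 0.0,
            mean_per_locus_all=mapping_count / len(loci) if loci else 0.0,
            aggregate_density_per_kb=mapping_count / total_kb if total_kb else 0.0,
        )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read a BED6 file into ``(name, GenomicInterval)`` pairs, file order.

    Coordinates are kept in the native BED 0-based half-open convention.
    Raises :class:`ParseError` naming the line number on malformed input.
    """
    records: list[tuple[str, GenomicInterval]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 6 BED fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((name, interval))
    return records


def write_bed(
    records: Iterable[tuple[str, GenomicInterval]], path: str | Path
) -> None:
    """Write ``(name, GenomicInterval)`` pairs as BED6 (score column 0)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, iv in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_interactions(
    path: str | Path, universe_path: str | Path | None = None
) -> InteractionTable:
    """Read a miRNA-target interaction TSV (mirna_id, target_id, target_class).

    Duplicate rows are collapsed (logged at info level). The miRNA universe
    is the union of edge miRNAs unless ``universe_path`` (one id per line)
    is supplied.
    """
    df = _read_tsv(path, ["mirna_id", "target_id", "target_class"])
    bad = set(df["target_class"]) - set(TARGET_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown target_class value(s) {sorted(bad)}")
    edges = list(
        df[["mirna_id", "target_id", "target_class"]].itertuples(index=False, name=None)
    )
    unique = set(edges)
    if len(unique) < len(edges):
        logger.info(
            "%s: collapsed %d duplicate interaction rows", path, len(edges) - len(unique)
        )
    universe = read_id_list(universe_path) if universe_path is not None else None
    return InteractionTable(unique, universe)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mirna_id\ttarget_id\ttarget_class\n")
        for mirna, target, cls in sorted(table.edges):
            fh.write(f"{mirna}\t{target}\t{cls}\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_disease_map(path: str | Path) -> DiseaseMiRNAMap:
    """Read a long-format disease-miRNA TSV (disease, mirna_id[, curated]).

    ``curated`` is 0/1; rows with 1 additionally populate the curated
    subset for their disease.
    """
    df = _read_tsv(path, ["disease", "mirna_id"])
    full: dict[str, set[str]] = {}
    curated: dict[str, set[str]] = {}
    has_curated = "curated" in df.columns
    for row in df.itertuples(index=False):
        full.setdefault(row.disease, set()).add(row.mirna_id)
        if has_curated and str(row.curated) == "1":
            curated.setdefault(row.disease, set()).add(row.mirna_id)
    return DiseaseMiRNAMap(
        {d: frozenset(s) for d, s in full.items()},
        {d: frozenset(s) for d, s in curated.items()},
    )


def write_disease_map(dmap: DiseaseMiRNAMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("disease\tmirna_id\tcurated\n")
        for disease in dmap.diseases():
            curated = dmap.curated_subset.get(disease, frozenset())
            for mirna in sorted(dmap.map[disease]):
                fh.write(f"{disease}\t{mirna}\t{int(mirna in curated)}\n")


def read_snps(
    path: str | Path, coordinate_convention: str = "1-based"
) -> list[SNPRecord]:
    """Read a SNP catalog TSV (rsid, chrom, pos[, trait]).

    ``coordinate_convention`` is ``"1-based"`` (dbSNP/GWAS-catalog exports;
    pos0 = pos - 1) or ``"0-based"``. Duplicate rsids raise an error
    listing the offenders.
    """
    if coordinate_convention not in ("1-based", "0-based"):
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    df = _read_tsv(path, ["rsid", "chrom", "pos"])
    dup = df["rsid"][df["rsid"].duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicate rsid(s): {sorted(dup)[:10]}")
    shift = 1 if coordinate_convention == "1-based" else 0
    has_trait = "trait" in df.columns
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.pos) - shift
        if pos < 0:
            raise ParseError(f"{path}: negative position for {row.rsid}")
        records.append(
            SNPRecord(row.rsid, row.chrom, pos, row.trait if has_trait else "")
        )
    return records


def write_snps(
    records: Iterable[SNPRecord],
    path: str | Path,
    coordinate_convention: str = "1-based",
) -> None:
    """Write a SNP catalog TSV in the requested coordinate convention."""
    if coordinate_convention not in ("1-based", "0-based"):
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    shift = 1 if coordinate_convention == "1-based" else 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rsid\tchrom\tpos\ttrait\n")
        for r in records:
            fh.write(f"{r.rsid}\t{r.chrom}\t{r.pos0 + shift}\t{r.trait}\n")


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    """Write enrichment calls as TSV; p-values in scientific notation with
    12+ significant digits."""
    cols = [
        "circ_id", "disease", "M_T", "m_c", "M_d", "m_d",
        "p_value", "m", "p_threshold", "significant",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(
                f"{r.circ_id}\t{r.disease}\t{r.M_T}\t{r.m_c}\t{r.M_d}\t{r.m_d}\t"
                f"{r.p:.12e}\t{r.m}\t{r.p_threshold:.12e}\t{r.significant}\n"
            )


def read_enrichment_results(path: str | Path) -> list[EnrichmentResult]:
    df = _read_tsv(path, ["circ_id", "disease", "M_T", "m_c", "M_d", "m_d",
                          "p_value", "m", "p_threshold", "significant"])
    return [
        EnrichmentResult(
            circ_id=row.circ_id,
            disease=row.disease,
            M_T=int(row.M_T),
            m_c=int(row.m_c),
            M_d=int(row.M_d),
            m_d=int(row.m_d),
            p=float(row.p_value),
            m=int(row.m),
            p_threshold=float(row.p_threshold),
            significant=row.significant == "True",
        )
        for row in df.itertuples(index=False)
    ]
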