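"""Synthetic inputs with planted ground truth for the whole pipeline.

Emulates the statistical structure of the real data sources — sparse
miRNA-target interactions with planted disease enrichment, Poisson
variant density per kb of circRNA locus, Poisson Ago-site counts per
circRNA, and sparse trait labelling of SNPs — without any sequence-level
simulation. Defaults are anchored to the published summary figures:
24.01 SNPs per kb, 2.658 Ago sites per circRNA, and a mean circRNA locus
of ~9,043 bp (217.13 mean SNPs per locus / 24.01 SNPs per kb).

Randomness uses a single root seed with named per-stream sub-seeds
(loci, disease sets, circRNA edges, mRNA/lncRNA edges, SNPs, traits, Ago
sites), so enabling or resizing one stage never perturbs another
stream's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    AgoSite,
    CircRNA,
    DiseaseMiRNAMap,
    GenomicInterval,
    InteractionTable,
    SNPRecord,
    write_bed,
    write_disease_map,
    write_id_list,
    write_interactions,
    write_snps,
)

logger = logging.getLogger(__name__)

_STREAMS = ("loci", "disease_sets", "edges", "mrna_lnc", "snps", "traits", "ago")


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Lengths are bp; rates are per kb (SNPs) or per circRNA (Ago sites).
    ``planted_pairs`` lists (circRNA index, disease index) pairs whose
    disease-miRNA edges occur with probability ``planted_edge_prob``
    instead of ``background_edge_prob``.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length_bp: int = 10_000_000
    n_circrnas: int = 200
    # lognormal length model; defaults give a mean of ~9,043 bp
    circ_length_log_mean: float = 8.7898
    circ_length_log_sd: float = 0.8
    min_circ_length: int = 200
    allow_locus_overlap: bool = False
    n_mirnas: int = 2000
    n_diseases: int = 10
    disease_set_size_range: tuple[int, int] = (30, 30)
    background_edge_prob: float = 0.01
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 2), (3, 3), (4, 4))
    planted_edge_prob: float = 0.5
    snp_rate_per_kb: float = 24.01
    n_intergenic_snps: int = 500
    trait_snp_fraction: float = 0.001
    ago_sites_per_circ_mean: float = 2.658
    ago_site_length_range: tuple[int, int] = (20, 40)
    n_mrnas: int = 500
    n_lncrnas: int = 200
    mrna_lncrna_edge_prob: float = 0.01

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        for name in ("n_chromosomes", "chromosome_length_bp"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_circrnas", "n_mirnas", "n_diseases", "n_mrnas",
                     "n_lncrnas", "n_intergenic_snps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigError("background_edge_prob must be in [0, 1]")
        if not self.background_edge_prob <= self.planted_edge_prob <= 1.0:
            raise ConfigError(
                "planted_edge_prob must satisfy background <= planted <= 1"
            )
        if self.snp_rate_per_kb <= 0:
            raise ConfigError("snp_rate_per_kb must be > 0")
        if self.ago_sites_per_circ_mean < 0:
            raise ConfigError("ago_sites_per_circ_mean must be >= 0")
        lo, hi = self.disease_set_size_range
        if not 1 <= lo <= hi <= max(self.n_mirnas, 1):
            raise ConfigError("disease_set_size_range infeasible for n_mirnas")
        lo, hi = self.ago_site_length_range
        if not 1 <= lo <= hi:
            raise ConfigError("ago_site_length_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.trait_snp_fraction <= 1.0:
            raise ConfigError("trait_snp_fraction must be in [0, 1]")
        if self.min_circ_length >= self.chromosome_length_bp:
            raise ConfigError("min_circ_length must be < chromosome_length_bp")
        # median locus length must fit on a chromosome
        if np.exp(self.circ_length_log_mean) >= self.chromosome_length_bp:
            raise ConfigError("typical circRNA length exceeds chromosome length")
        for c, d in self.planted_pairs:
            if not (0 <= c < self.n_circrnas and 0 <= d < self.n_diseases):
                raise ConfigError(f"planted pair ({c}, {d}) out of range")


@dataclass(frozen=True)
class PlantedTruth:
    """The planted (circ_id, disease) pairs and their realized m_d."""

    pairs: tuple[tuple[str, str], ...]
    realized_m_d: dict[tuple[str, str], int]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    circrnas: list[CircRNA]
    interactions: InteractionTable
    diseases: DiseaseMiRNAMap
    snps: list[SNPRecord]  # genome-wide catalog (trait empty)
    trait_snps: list[SNPRecord]  # trait-labelled catalog
    ago_sites: list[AgoSite]
    truth: PlantedTruth

    @property
    def loci(self) -> list[tuple[str, GenomicInterval]]:
        return [(c.circ_id, c.locus) for c in self.circrnas]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(n)]


def _disease_names(n: int) -> list[str]:
    return [f"disease_{i:02d}" for i in range(n)]


def _sample_loci(config: SimulationConfig, rng: np.random.Generator) -> list[CircRNA]:
    placed: dict[int, list[tuple[int, int]]] = {c: [] for c in range(config.n_chromosomes)}
    circrnas = []
    for i in range(config.n_circrnas):
        for _attempt in range(1000):
            chrom_i = int(rng.integers(config.n_chromosomes))
            length = int(round(rng.lognormal(config.circ_length_log_mean,
                                             config.circ_length_log_sd)))
            length = max(config.min_circ_length, length)
            if length >= config.chromosome_length_bp:
                continue
            start = int(rng.integers(0, config.chromosome_length_bp - length))
            end = start + length
            if not config.allow_locus_overlap and any(
                s < end and start < e for s, e in placed[chrom_i]
            ):
                continue
            placed[chrom_i].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            circrnas.append(
                CircRNA(f"circ_{i:04d}",
                        GenomicInterval(f"chr{chrom_i + 1}", start, end, strand))
            )
            break
        else:
            raise ConfigError(
                f"could not place circRNA {i} without overlap after 1000 tries; "
                "loci too dense for the chromosome sizes"
            )
    return circrnas


def simulate_interactions(
    config: SimulationConfig,
) -> tuple[InteractionTable, DiseaseMiRNAMap, PlantedTruth]:
    """Sample the interaction table, disease map and planted truth only.

    Uses the same per-stream sub-seeds as :func:`generate_dataset`, so the
    result is identical to the corresponding slice of the full dataset.
    """
    config.validate()
    rngs = _streams(config.seed)
    mirnas = _mirna_ids(config.n_mirnas)
    diseases = _disease_names(config.n_diseases)
    circ_ids = [f"circ_{i:04d}" for i in range(config.n_circrnas)]

    rng = rngs["disease_sets"]
    lo, hi = config.disease_set_size_range
    disease_sets: dict[str, frozenset[str]] = {}
    members: list[np.ndarray] = []
    for d in diseases:
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.n_mirnas, size=size, replace=False)
        members.append(np.sort(idx))
        disease_sets[d] = frozenset(mirnas[j] for j in idx)

    rng = rngs["edges"]
    adj = rng.random((config.n_circrnas, config.n_mirnas)) < config.background_edge_prob
    for c, d in config.planted_pairs:
        cols = members[d]
        adj[c, cols] = rng.random(cols.size) < config.planted_edge_prob

    edges = [
        (mirnas[j], circ_ids[i], "circRNA")
        for i, j in np.argwhere(adj)
    ]

    rng = rngs["mrna_lnc"]
    targets = (
        [(f"gene_{i:04d}", "mRNA") for i in range(config.n_mrnas)]
        + [(f"lnc_{i:04d}", "lncRNA") for i in range(config.n_lncrnas)]
    )
    if targets:
        tadj = rng.random((len(targets), config.n_mirnas)) < config.mrna_lncrna_edge_prob
        edges += [
            (mirnas[j], targets[i][0], targets[i][1])
            for i, j in np.argwhere(tadj)
        ]

    table = InteractionTable(edges, mirna_universe=mirnas)
    truth_pairs = tuple((circ_ids[c], diseases[d]) for c, d in config.planted_pairs)
    realized = {
        (circ_ids[c], diseases[d]): int(adj[c, members[d]].sum())
        for c, d in config.planted_pairs
    }
    dmap = DiseaseMiRNAMap(disease_sets)
    return table, dmap, PlantedTruth(truth_pairs, realized)


def generate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full synthetic dataset; optionally write it to ``outdir``.

    Fully reproducible: the same config (seed included) yields
    byte-identical output files.
    """
    config.validate()
    rngs = _streams(config.seed)
    circrnas = _sample_loci(config, rngs["loci"])
    interactions, dmap, truth = simulate_interactions(config)

    # SNPs: homogeneous Poisson process at snp_rate_per_kb inside each locus,
    # plus an intergenic background rejected out of the loci
    rng = rngs["snps"]
    snps: list[SNPRecord] = []
    for circ in circrnas:
        lam = config.snp_rate_per_kb * circ.locus.length() / 1000.0
        n = int(rng.poisson(lam))
        if n:
            positions = np.sort(rng.integers(circ.locus.start, circ.locus.end, size=n))
            for pos in positions:
                snps.append(SNPRecord(f"rs{len(snps):07d}", circ.locus.chrom, int(pos)))
    occupied: dict[str, list[tuple[int, int]]] = {}
    for circ in circrnas:
        occupied.setdefault(circ.locus.chrom, []).append(
            (circ.locus.start, circ.locus.end)
        )
    placed = 0
    while placed < config.n_intergenic_snps:
        chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        pos = int(rng.integers(config.chromosome_length_bp))
        if any(s <= pos < e for s, e in occupied.get(chrom, ())):
            continue
        snps.append(SNPRecord(f"rs{len(snps):07d}", chrom, pos))
        placed += 1

    rng = rngs["traits"]
    disease_names = dmap.diseases()
    trait_snps = []
    if disease_names and config.trait_snp_fraction > 0:
        labelled = rng.random(len(snps)) < config.trait_snp_fraction
        traits = rng.integers(len(disease_names), size=len(snps))
        trait_snps = [
            SNPRecord(s.rsid, s.chrom, s.pos0, disease_names[traits[i]])
            for i, s in enumerate(snps)
            if labelled[i]
        ]

    rng = rngs["ago"]
    lo, hi = config.ago_site_length_range
    ago_sites: list[AgoSite] = []
    for circ in circrnas:
        n = int(rng.poisson(config.ago_sites_per_circ_mean))
        for _ in range(n):
            length = min(int(rng.integers(lo, hi + 1)), circ.locus.length())
            start = int(rng.integers(circ.locus.start, circ.locus.end - length + 1))
            ago_sites.append(
                AgoSite(
                    f"ago_{len(ago_sites):05d}",
                    GenomicInterval(circ.locus.chrom, start, start + length,
                                    circ.locus.strand),
                )
            )

    dataset = SyntheticDataset(
        config=config,
        circrnas=circrnas,
        interactions=interactions,
        diseases=dmap,
        snps=snps,
        trait_snps=trait_snps,
        ago_sites=ago_sites,
        truth=truth,
    )
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


DATASET_FILES = (
    "circrnas.bed",
    "ago_sites.bed",
    "interactions.tsv",
    "mirna_universe.txt",
    "diseases.tsv",
    "snps.tsv",
    "trait_snps.tsv",
    "truth.json",
)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in the pipeline's input formats plus a JSON
    sidecar holding the config and the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(dataset.loci, outdir / "circrnas.bed")
    write_bed([(s.site_id, s.locus) for s in dataset.ago_sites],
              outdir / "ago_sites.bed")
    write_interactions(dataset.interactions, outdir / "interactions.tsv")
    write_id_list(dataset.interactions.mirna_universe, outdir / "mirna_universe.txt")
    write_disease_map(dataset.diseases, outdir / "diseases.tsv")
    write_snps(dataset.snps, outdir / "snps.tsv")
    write_snps(dataset.trait_snps, outdir / "trait_snps.tsv")
    sidecar = {
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(dataset.config).items()
        },
        "planted_pairs": [list(p) for p in dataset.truth.pairs],
        "realized_m_d": {
            f"{c}|{d}": m for (c, d), m in sorted(dataset.truth.realized_m_d.items())
        },
    }
    with open(outdir / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def realized_statistics(dataset: SyntheticDataset) -> dict[str, float]:
    """Recompute realized rates from the generated data.

    Under the configured model each is within ~3 standard errors of its
    configured value: SNP density per kb of locus, Ago sites per circRNA,
    background circRNA-miRNA edge probability and mean locus length.
    """
    n_circ = len(dataset.circrnas)
    total_kb = sum(c.locus.length() for c in dataset.circrnas) / 1000.0
    n_locus_snps = len(dataset.snps) - dataset.config.n_intergenic_snps
    planted_circs = {c for (c, _d) in dataset.truth.pairs}
    background_edges = sum(
        1
        for m, t, cls in dataset.interactions.edges
        if cls == "circRNA" and t not in planted_circs
    )
    n_background_circ = n_circ - len(planted_circs)
    cells = n_background_circ * dataset.config.n_mirnas
    return {
        "snp_density_per_kb": n_locus_snps / total_kb if total_kb else 0.0,
        "ago_sites_per_circ": len(dataset.ago_sites) / n_circ if n_circ else 0.0,
        "background_edge_prob": background_edges / cells if cells else 0.0,
        "mean_circ_length_bp": (total_kb * 1000.0 / n_circ) if n_circ else 0.0,
        "n_snps": float(len(dataset.snps)),
        "n_trait_snps": float(len(dataset.trait_snps)),
    }
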