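"""Per-disease miRNA-mediated post-transcriptional interaction networks.

For a disease, the network contains the disease's miRNAs (after an
optional curation filter) and every circRNA, mRNA and lncRNA target any
of them hits; edges run miRNA -> target only, making the graph bipartite.
Disease miRNAs without any target remain as isolated nodes. Target node
identity is the (id, class) pair: an mRNA and a lncRNA sharing a symbol
stay distinct.

Exports are SIF (primary; loads directly into Cytoscape-class viewers)
and GraphML with node-class attributes, both with deterministic
lexicographic ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .data_io import DiseaseMiRNAMap, InteractionTable

logger = logging.getLogger(__name__)

NODE_CLASSES = ("miRNA", "circRNA", "mRNA", "lncRNA")


@dataclass
class DiseaseNetwork:
    disease: str
    nodes: set[tuple[str, str]]  # (id, node_class)
    edges: set[tuple[str, str, str]]  # (mirna_id, target_id, target_class)

    def __post_init__(self) -> None:
        node_ids = self.nodes
        for mirna, target, cls in self.edges:
            if (mirna, "miRNA") not in node_ids or (target, cls) not in node_ids:
                raise ValueError(f"edge ({mirna}, {target}, {cls}) has missing endpoint")
            if mirna == target and cls == "miRNA":
                raise ValueError("self-loop")

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, c in self.nodes if c == "miRNA"}


def build_disease_network(
    disease: str,
    diseases: DiseaseMiRNAMap,
    interactions: InteractionTable,
    curated_only: bool = False,
) -> DiseaseNetwork:
    """Restrict the interaction table to one disease's miRNAs.

    Nodes are exactly the disease's miRNAs (post-filter) plus every target
    any of them hits; edges are exactly the table rows whose miRNA belongs
    to the disease. A curated-only request without a curated subset yields
    an empty network with a warning.
    """
    mirnas = diseases.mirnas(disease, curated_only=curated_only)
    if mirnas is None or not mirnas:
        logger.warning(
            "disease %r: empty miRNA set%s; returning empty network",
            disease, " (no curated subset)" if mirnas is None else "",
        )
        return DiseaseNetwork(disease, set(), set())
    edges = {(m, t, c) for m, t, c in interactions.edges if m in mirnas}
    nodes = {(m, "miRNA") for m in mirnas}
    nodes |= {(t, c) for _, t, c in edges}
    return DiseaseNetwork(disease, nodes, edges)


def export_sif(network: DiseaseNetwork, path: str | Path) -> None:
    """One line per edge: ``mirna<TAB>targets_<class><TAB>target``, sorted
    lexicographically — byte-stable across reruns."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for mirna, target, cls in sorted(network.edges):
            fh.write(f"{mirna}\ttargets_{cls}\t{target}\n")


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Inverse of :func:`export_sif`: recover (mirna, target, class) edges."""
    edges = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            mirna, relation, target = line.rstrip("\n").split("\t")
            edges.add((mirna, target, relation.removeprefix("targets_")))
    return edges


def export_graphml(network: DiseaseNetwork, path: str | Path) -> None:
    g = nx.DiGraph(disease=network.disease)
    # node key embeds the class so shared symbols stay distinct
    for node_id, cls in sorted(network.nodes):
        g.add_node(f"{cls}:{node_id}", node_class=cls, label=node_id)
    for mirna, target, cls in sorted(network.edges):
        g.add_edge(f"miRNA:{mirna}", f"{cls}:{target}", target_class=cls)
    nx.write_graphml(g, path)


def write_node_attributes(network: DiseaseNetwork, path: str | Path) -> None:
    """TSV companion to the SIF export: node_id, class."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tclass\n")
        for node_id, cls in sorted(network.nodes):
            fh.write(f"{node_id}\t{cls}\n")


@dataclass
class DegreeSummary:
    """Distinct target counts per class plus per-node degree."""

    circrna_count: int
    mrna_count: int
    lncrna_count: int
    mirna_count: int
    degrees: dict[tuple[str, str], int]  # (id, class) -> degree


def network_degree_summary(network: DiseaseNetwork) -> DegreeSummary:
    degrees = {node: 0 for node in network.nodes}
    for mirna, target, cls in network.edges:
        degrees[(mirna, "miRNA")] += 1
        degrees[(target, cls)] += 1
    counts = {c: sum(1 for _, cls in network.nodes if cls == c) for c in NODE_CLASSES}
    return DegreeSummary(
        circrna_count=counts["circRNA"],
        mrna_count=counts["mRNA"],
        lncrna_count=counts["lncRNA"],
        mirna_count=counts["miRNA"],
        degrees=degrees,
    )


def write_degree_summary(summary: DegreeSummary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tclass\tdegree\n")
        for (node_id, cls), deg in sorted(summary.degrees.items()):
            fh.write(f"{node_id}\t{cls}\t{deg}\n")
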