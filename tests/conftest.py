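from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circtraits import (
    DiseaseMiRNAMap,
    GenomicInterval,
    InteractionTable,
    SimulationConfig,
    SNPRecord,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture()
def small_table() -> InteractionTable:
    """Universe {a..e}; circX binds {a,b,c}; plus one mRNA and one lncRNA edge."""
    return InteractionTable(
        edges=[
            ("a", "circX", "circRNA"),
            ("b", "circX", "circRNA"),
            ("c", "circX", "circRNA"),
            ("a", "TP53", "mRNA"),
            ("d", "HOTAIR", "lncRNA"),
        ],
        mirna_universe=["a", "b", "c", "d", "e"],
    )


@pytest.fixture()
def small_diseases() -> DiseaseMiRNAMap:
    return DiseaseMiRNAMap(
        {"glioma": frozenset({"b", "c", "d"}), "asthma": frozenset({"e"})},
        curated_subset={"glioma": frozenset({"b", "c"})},
    )


@pytest.fixture()
def toy_loci() -> list[tuple[str, GenomicInterval]]:
    return [
        ("circA", GenomicInterval("chr1", 100, 200, "+")),
        ("circB", GenomicInterval("chr1", 150, 400, "-")),
        ("circC", GenomicInterval("chr2", 0, 1000, "+")),
    ]


def random_loci(rng: np.random.Generator, n: int, n_chrom: int = 3,
                span: int = 100_000) -> list[tuple[str, GenomicInterval]]:
    loci = []
    for i in range(n):
        start = int(rng.integers(0, span - 2))
        end = int(rng.integers(start + 1, min(start + 5000, span)))
        loci.append(
            (f"L{i:05d}",
             GenomicInterval(f"chr{int(rng.integers(n_chrom)) + 1}", start, end,
                             "+" if rng.random() < 0.5 else "-"))
        )
    return loci


def random_snps(rng: np.random.Generator, n: int, n_chrom: int = 3,
                span: int = 100_000) -> list[SNPRecord]:
    return [
        SNPRecord(f"rs{i:06d}", f"chr{int(rng.integers(n_chrom)) + 1}",
                  int(rng.integers(span)))
        for i in range(n)
    ]


@pytest.fixture()
def fast_config() -> SimulationConfig:
    """A scaled-down simulation for quick end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_circrnas=30,
        n_mirnas=300,
        n_diseases=4,
        disease_set_size_range=(10, 10),
        planted_pairs=((0, 0), (1, 1)),
        n_mrnas=50,
        n_lncrnas=20,
        n_intergenic_snps=50,
    )
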