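"""Hypergeometric enrichment of disease-associated miRNA interactions.

A circRNA acting as a miRNA sponge is scored for a disease by asking: of
the m_c miRNAs that bind the circRNA, drawn without replacement from a
universe of M_T miRNAs of which M_d are associated with the disease, how
surprising is observing m_d or more disease miRNAs? The upper-tail
hypergeometric probability is

    p = sum_{i=m_d}^{min(m_c, M_d)} C(M_d, i) C(M_T - M_d, m_c - i) / C(M_T, m_c)

and a circRNA is called associated when p < 0.05 / m, where m is the
number of circRNAs interacting with at least one miRNA of the concerned
disease (per-disease Bonferroni family).

The tail is evaluated in log space (cached log-factorials + logsumexp),
which is stable for universes of many thousands of miRNAs. An exact
rational evaluation is kept in the test suite as an independent oracle.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

from .data_io import DiseaseMiRNAMap, EnrichmentResult, InteractionTable

logger = logging.getLogger(__name__)

# log(n!) cache, grown geometrically on demand
_LOGFACT = [math.lgamma(n + 1.0) for n in range(1024)]


def _logfact(n_max: int) -> list[float]:
    if n_max >= len(_LOGFACT):
        _LOGFACT.extend(
            math.lgamma(n + 1.0)
            for n in range(len(_LOGFACT), max(n_max + 1, 2 * len(_LOGFACT)))
        )
    return _LOGFACT


def hypergeom_tail_p(M_T: int, m_c: int, M_d: int, m_d: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m_d).

    X is the number of disease-associated miRNAs among the m_c partners of
    a circRNA, for M_d disease miRNAs in a universe of M_T. Requires
    0 <= m_d <= min(m_c, M_d), m_c <= M_T, M_d <= M_T, M_T >= 1.
    """
    if M_T < 1:
        raise ValueError(f"need M_T >= 1, got M_T={M_T}")
    if not 0 <= m_c <= M_T:
        raise ValueError(f"need 0 <= m_c <= M_T, got m_c={m_c}, M_T={M_T}")
    if not 0 <= M_d <= M_T:
        raise ValueError(f"need 0 <= M_d <= M_T, got M_d={M_d}, M_T={M_T}")
    if not 0 <= m_d <= min(m_c, M_d):
        raise ValueError(
            f"need 0 <= m_d <= min(m_c, M_d), got m_d={m_d}, "
            f"m_c={m_c}, M_d={M_d}"
        )
    # support of X is [max(0, m_c - (M_T - M_d)), min(m_c, M_d)]
    lo_support = max(0, m_c - (M_T - M_d))
    hi = min(m_c, M_d)
    if m_d <= lo_support:
        return 1.0  # tail covers the whole support
    lf = _logfact(M_T)
    base = lf[M_d] + lf[M_T - M_d] + lf[m_c] + lf[M_T - m_c] - lf[M_T]
    log_terms = [
        base - lf[i] - lf[M_d - i] - lf[m_c - i] - lf[M_T - M_d - m_c + i]
        for i in range(m_d, hi + 1)
    ]
    # logsumexp with compensated accumulation of the rescaled terms
    peak = max(log_terms)
    total = math.fsum(math.exp(t - peak) for t in log_terms)
    return min(1.0, math.exp(peak) * total)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-disease significance threshold alpha / m for a family of m
    tested circRNAs. A disease with no interacting circRNA is never
    tested, so m must be >= 1."""
    if m < 1:
        raise ValueError(f"need m >= 1 tested circRNAs, got m={m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def count_parameters(
    interactions: InteractionTable,
    diseases: DiseaseMiRNAMap,
    circ_id: str,
    disease: str,
) -> tuple[int, int, int, int]:
    """The (M_T, m_c, M_d, m_d) counts for one (circRNA, disease) test.

    M_d is intersected with the miRNA universe: disease miRNAs absent from
    the universe cannot appear among a circRNA's partners and would make
    the test ill-defined.
    """
    partners = interactions.mirnas_of_target(circ_id, "circRNA")
    if not partners:
        raise KeyError(f"unknown or partner-less circRNA {circ_id!r}")
    disease_set = diseases.mirnas(disease) & interactions.mirna_universe
    return (
        len(interactions.mirna_universe),
        len(partners),
        len(disease_set),
        len(partners & disease_set),
    )


def call_disease_associations(
    interactions: InteractionTable,
    diseases: DiseaseMiRNAMap,
    curated_only: bool = False,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Run the enrichment test for every disease against every circRNA
    that interacts with at least one of its miRNAs.

    For each disease d, the Bonferroni family size m is the number of
    circRNAs with >= 1 edge to a miRNA of d (recomputed after any curation
    filter); exactly those m circRNAs are tested at threshold alpha/m with
    strict inequality. Diseases whose (filtered) miRNA set is empty, or
    empty after intersection with the universe, are skipped with a logged
    warning. Output is sorted by (disease, ascending p, circ_id).
    """
    universe = interactions.mirna_universe
    M_T = len(universe)
    # partner sets per circRNA, restricted to circRNA-class targets
    circ_partners = {
        c: interactions.mirnas_of_target(c, "circRNA")
        for c in interactions.target_ids("circRNA")
    }
    results: list[EnrichmentResult] = []
    for disease in diseases.diseases():
        disease_set = diseases.mirnas(disease, curated_only=curated_only)
        if disease_set is None:
            logger.warning(
                "disease %r skipped: no curated miRNA subset", disease
            )
            continue
        dropped = len(disease_set - universe)
        if dropped:
            logger.info(
                "disease %r: %d miRNA(s) outside the universe dropped",
                disease, dropped,
            )
        disease_set = disease_set & universe
        if not disease_set:
            logger.warning(
                "disease %r skipped: miRNA set empty after filtering", disease
            )
            continue
        tested = {
            c: partners
            for c, partners in circ_partners.items()
            if partners & disease_set
        }
        if not tested:
            continue  # no circRNA interacts with this disease's miRNAs
        m = len(tested)
        threshold = bonferroni_threshold(m, alpha)
        M_d = len(disease_set)
        for circ_id, partners in tested.items():
            m_c = len(partners)
            m_d = len(partners & disease_set)
            p = hypergeom_tail_p(M_T, m_c, M_d, m_d)
            results.append(
                EnrichmentResult(
                    circ_id=circ_id,
                    disease=disease,
                    M_T=M_T,
                    m_c=m_c,
                    M_d=M_d,
                    m_d=m_d,
                    p=p,
                    m=m,
                    p_threshold=threshold,
                    significant=p < threshold,
                )
            )
    results.sort(key=lambda r: (r.disease, r.p, r.circ_id))
    return results


def significant_pairs(
    results: Sequence[EnrichmentResult],
) -> set[tuple[str, str]]:
    """The (circ_id, disease) pairs called significant."""
    return {(r.circ_id, r.disease) for r in results if r.significant}
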