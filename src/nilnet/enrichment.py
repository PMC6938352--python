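"""Hypergeometric over-representation of gene lists against an annotation
universe, with Benjamini-Hochberg correction.

For a term annotated to K of the N universe genes, and a list of n genes of
which k carry the term, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n), computed in log space via the
regularized survival function.  Terms with zero hits in the list are not
tested by default (this sets the BH family size), matching common practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

from .data_io import GeneSetAnnotation
from .de_stepwise import bh_adjust


@dataclass
class EnrichmentRecord:
    term: str
    N: int
    K: int
    n: int
    k: int
    p: float
    p_adj: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(gene_list: set[str], annotation: GeneSetAnnotation, alpha: float = 0.05,
           test_zero_hit_terms: bool = False) -> list[EnrichmentRecord]:
    """Test every annotation term for over-representation in the gene list.

    Genes outside the annotation universe are dropped with a warning; the
    result is sorted by adjusted p-value.
    """
    universe = annotation.universe
    outside = set(gene_list) - universe
    if outside:
        warnings.warn(f"{len(outside)} gene(s) outside the annotation universe dropped")
    effective = set(gene_list) & universe
    if not effective:
        raise ValueError("gene list is empty after restricting to the universe")
    N, n = len(universe), len(effective)
    records = []
    for term in sorted(annotation.terms):
        members = annotation.genes_with_term(term)
        K = len(members)
        k = len(members & effective)
        if k == 0 and not test_zero_hit_terms:
            continue
        records.append(EnrichmentRecord(term, N, K, n, k,
                                        hypergeom_upper_tail(N, K, n, k), 1.0))
    adj = bh_adjust([r.p for r in records])
    for r, a in zip(records, adj):
        r.p_adj = float(a)
    records.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return records
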