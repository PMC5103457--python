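"""Hypergeometric over-representation test with Bonferroni correction.

For a gene list of size n drawn from a universe of N genes, a term
annotating K universe genes and hitting k list genes is scored by the
upper hypergeometric tail P(X >= k). Only terms with K >= 1 and k >= 1 are
tested; Bonferroni multiplies by the number m of terms actually tested.
Terms are significant below the adjusted cutoff (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .io_formats import AnnotationMap


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    k: int  # term genes in the list
    n: int  # list size
    K: int  # term genes in the universe
    N: int  # universe size
    raw_p: float
    adj_p: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.adj_p < self.alpha


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list: Iterable[str],
    annotation: AnnotationMap,
    universe: Iterable[str] | None = None,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every term represented in the gene list for over-representation.

    The universe defaults to all genes carrying >= 1 annotation in the map;
    list genes must belong to the universe (offenders are reported). Results
    come back sorted by raw p, then term id.
    """
    genes = set(gene_list)
    universe_set = set(universe) if universe is not None else annotation.annotated_genes
    offenders = sorted(genes - universe_set)
    if offenders:
        raise ValueError(f"genes in list absent from universe: {offenders}")
    n = len(genes)
    N = len(universe_set)

    tested: list[tuple[str, int, int]] = []
    for term in sorted(annotation.term_ids):
        term_genes = annotation.genes_with_term(term) & universe_set
        K = len(term_genes)
        k = len(term_genes & genes)
        if K >= 1 and k >= 1:
            tested.append((term, K, k))
    m = len(tested)

    results = []
    for term, K, k in tested:
        raw_p = hypergeom_tail(k, N, K, n)
        results.append(
            EnrichmentResult(
                term_id=term,
                description=annotation.term_descriptions.get(term, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                raw_p=raw_p,
                adj_p=min(1.0, raw_p * m),
                alpha=alpha,
            )
        )
    results.sort(key=lambda r: (r.raw_p, r.term_id))
    return results
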