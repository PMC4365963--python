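"""Hierarchy-aware GO enrichment and flat pathway enrichment for clusters.

Every term is tested by a one-sided Fisher exact test (hypergeometric tail)
for over-representation of cluster genes among the term's annotated genes.
Two GO modes are offered: ``classic`` tests each biological-process term
independently; ``elim`` decorrelates the DAG by processing terms bottom-up
(deepest level first) and, whenever a term comes out significant at
``elim_alpha``, removing its annotated cluster genes from all of its
ancestors before those are tested. Reported results are filtered to raw
p < 0.05 with at least 5 annotated cluster genes; no multiple-testing
correction is applied on top of that filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom

from .io_formats import AnnotationTable, OntologyGraph

__all__ = [
    "EnrichmentResult",
    "fisher_exact",
    "go_enrich",
    "pathway_enrich",
]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_enriched_genes: int
    p_value: float
    genes: tuple[str, ...]


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    [[a, b], [c, d]]: the exact hypergeometric tail P(X >= a) with the
    table's margins."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if a == 0:
        return 1.0  # P(X >= 0) regardless of margins
    total = a + b + c + d
    return float(hypergeom.sf(a - 1, total, a + b, a + c))


def _term_levels(dag: OntologyGraph, terms) -> dict[str, int]:
    """Longest-path depth from a root for each term (roots at level 0)."""
    levels: dict[str, int] = {}
    for t in nx.topological_sort(dag.graph.reverse(copy=False)):
        # reverse graph: edges parent -> child, so parents come first
        parents = [p for p, _ in dag.parents(t)]
        levels[t] = 0 if not parents else 1 + max(levels[p] for p in parents)
    return {t: levels[t] for t in terms if t in levels}


def _test_term(
    term_genes: frozenset[str] | set[str],
    cluster: set[str],
    background_size: int,
) -> tuple[int, float]:
    a = len(term_genes & cluster)
    b = len(term_genes) - a
    c = len(cluster) - a
    d = background_size - a - b - c
    return a, fisher_exact(a, b, c, d)


def go_enrich(
    cluster_genes,
    background_genes,
    dag: OntologyGraph,
    ann: AnnotationTable,
    algorithm: str = "elim",
    elim_alpha: float = 0.01,
    alpha: float = 0.05,
    min_genes: int = 5,
    namespace: str = "biological_process",
) -> list[EnrichmentResult]:
    """GO enrichment of a cluster against a gene background.

    ``ann`` must already be true-path propagated (every gene annotated to all
    ancestors of its direct terms). Only terms of the requested namespace are
    tested. Results satisfy p < ``alpha`` and >= ``min_genes`` annotated
    cluster genes, sorted by p-value.
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not cluster <= background:
        missing = sorted(cluster - background)[0]
        raise ValueError(f"cluster gene {missing!r} absent from background")
    term_genes = {
        t: set(gs) & background for t, gs in ann.term_to_genes().items()
    }
    testable = [
        t
        for t in term_genes
        if term_genes[t]
        and dag.resolve(t) in dag.graph
        and dag.namespaces.get(dag.resolve(t), namespace) == namespace
    ]
    results: list[EnrichmentResult] = []
    if algorithm == "classic":
        order = sorted(testable)
        removed: dict[str, set[str]] = {}
    elif algorithm == "elim":
        levels = _term_levels(dag, [dag.resolve(t) for t in testable])
        # deepest first; ties broken by ascending term id
        order = sorted(testable, key=lambda t: (-levels[dag.resolve(t)], t))
        removed = {t: set() for t in testable}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    for t in order:
        genes_t = term_genes[t] - removed.get(t, set())
        a, p = _test_term(genes_t, cluster, len(background))
        if algorithm == "elim" and p < elim_alpha:
            explained = genes_t & cluster
            for anc in dag.ancestors(t, include_self=False):
                if anc in removed:
                    removed[anc] |= explained
        if p < alpha and a >= min_genes:
            results.append(
                EnrichmentResult(
                    term_id=t,
                    term_name=dag.names.get(dag.resolve(t), t),
                    n_enriched_genes=a,
                    p_value=p,
                    genes=tuple(sorted(genes_t & cluster)),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def pathway_enrich(
    cluster_genes,
    background_genes,
    pathway_map: AnnotationTable,
    alpha: float = 0.05,
    min_genes: int = 5,
    names: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Flat Fisher enrichment over a pathway catalogue (no hierarchy)."""
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not cluster <= background:
        missing = sorted(cluster - background)[0]
        raise ValueError(f"cluster gene {missing!r} absent from background")
    names = names or {}
    results = []
    for pw, genes in sorted(pathway_map.term_to_genes().items()):
        genes = set(genes) & background
        if not genes:
            continue
        a, p = _test_term(genes, cluster, len(background))
        if p < alpha and a >= min_genes:
            results.append(
                EnrichmentResult(
                    term_id=pw,
                    term_name=names.get(pw, pw),
                    n_enriched_genes=a,
                    p_value=p,
                    genes=tuple(sorted(genes & cluster)),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
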