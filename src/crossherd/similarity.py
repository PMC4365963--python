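"""Physical and functional similarity between co-expression clusters.

Physical similarity between two clusters is the hypergeometric upper-tail
probability of their gene overlap within a common universe. Functional
similarity compares the clusters' enriched GO term sets through the Wang
graph-based semantic similarity (edge weights 0.8 for ``is_a`` and 0.6 for
``part_of``) combined by the best-match average (BMA); its significance is
judged against an empirical null of term sets drawn at random from the
annotation pool, with ``p = #{sim_RAND > sim_CLUS} / N`` (N = 10,000 by
default; ties do not count against significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "WangSimilarity",
    "hypergeom_overlap",
    "wang_similarity",
    "bma_combine",
    "term_set_similarity",
    "sample_null",
    "empirical_pvalue",
    "similarity_graphs",
]

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def hypergeom_overlap(
    cluster_a, cluster_b, universe_size: int
) -> tuple[int, float]:
    """Gene overlap of two clusters and its hypergeometric upper-tail p.

    ``p = P(X >= k)`` for X ~ Hypergeometric(universe, |A|, |B|); disjoint
    clusters give p = 1.
    """
    a, b = set(cluster_a), set(cluster_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("cluster larger than the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p


class WangSimilarity:
    """Wang graph-based GO term similarity with cached semantic contributions.

    The S-value of term t in the ancestor closure of A is the best product of
    edge weights along a path from A up to t (S_A(A) = 1); the similarity of
    A and B is the summed S-values of their shared closure terms divided by
    the two closures' total semantic values.
    """

    def __init__(
        self,
        dag: OntologyGraph,
        w_is_a: float = 0.8,
        w_part_of: float = 0.6,
    ) -> None:
        self.dag = dag
        self.weights = {"is_a": w_is_a, "part_of": w_part_of}
        self._cache: dict[str, dict[str, float]] = {}

    def svalues(self, term: str) -> dict[str, float]:
        t = self.dag.resolve(term)
        if t not in self.dag.graph:
            raise KeyError(f"unknown term {term!r}")
        if t in self._cache:
            return self._cache[t]
        closure = self.dag.ancestors(t, include_self=True)
        sub = self.dag.graph.subgraph(closure)
        s = {t: 1.0}
        for node in nx.topological_sort(sub):  # children before parents
            if node not in s:
                continue
            for parent in sub.successors(node):
                w = self.weights[sub.edges[node, parent]["relation"]]
                cand = w * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._cache[t] = s
        return s

    def similarity(self, term_a: str, term_b: str) -> float:
        sa = self.svalues(term_a)
        sb = self.svalues(term_b)
        common = sa.keys() & sb.keys()
        if not common:
            return 0.0
        num = sum(sa[t] + sb[t] for t in common)
        return num / (sum(sa.values()) + sum(sb.values()))

    def matrix(self, terms_a, terms_b) -> np.ndarray:
        return np.array(
            [[self.similarity(a, b) for b in terms_b] for a in terms_a]
        )


def wang_similarity(
    term_a: str,
    term_b: str,
    dag: OntologyGraph,
    w_is_a: float = 0.8,
    w_part_of: float = 0.6,
) -> float:
    """Wang similarity of two GO terms (see :class:`WangSimilarity`)."""
    return WangSimilarity(dag, w_is_a, w_part_of).similarity(term_a, term_b)


def bma_combine(sim_matrix: np.ndarray) -> float:
    """Best-match average of an m x k term-pair similarity matrix:
    ``(sum_i max_j m[i,j] + sum_j max_i m[i,j]) / (m + k)``."""
    mat = np.asarray(sim_matrix, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("similarity matrix must be non-empty and 2-D")
    m, k = mat.shape
    return float((mat.max(axis=1).sum() + mat.max(axis=0).sum()) / (m + k))


def term_set_similarity(terms_a, terms_b, wang: WangSimilarity) -> float:
    """Wang + BMA similarity between two GO term sets (sim_CLUS)."""
    terms_a, terms_b = list(terms_a), list(terms_b)
    if not terms_a or not terms_b:
        raise ValueError("term sets must be non-empty")
    return bma_combine(wang.matrix(terms_a, terms_b))


def sample_null(
    term_pool,
    observed_sizes,
    n_draws: int,
    seed: int,
    wang: WangSimilarity,
) -> np.ndarray:
    """Empirical null of term-set similarities (sim_RAND).

    Each draw picks two set sizes uniformly from ``observed_sizes``, samples
    two term sets without replacement from the pool, and records their
    Wang+BMA similarity. Reproducible from ``seed``.
    """
    pool = sorted(set(term_pool))
    sizes = [int(s) for s in observed_sizes]
    if not pool:
        raise ValueError("empty term pool")
    if not sizes:
        raise ValueError("no observed sizes")
    if max(sizes) > len(pool):
        raise ValueError("requested set size exceeds the term pool")
    if n_draws < 100:
        raise ValueError("need at least 100 null draws")
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        na = sizes[rng.integers(len(sizes))]
        nb = sizes[rng.integers(len(sizes))]
        set_a = [pool[j] for j in rng.choice(len(pool), size=na, replace=False)]
        set_b = [pool[j] for j in rng.choice(len(pool), size=nb, replace=False)]
        out[i] = term_set_similarity(set_a, set_b, wang)
    return out


def empirical_pvalue(sim_clus: float, null_sample: np.ndarray) -> float:
    """``p = #{sim_RAND > sim_CLUS} / N``; ties favour significance."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    return float((null_sample > sim_clus).sum() / null_sample.size)


@dataclass
class SimilarityResult:
    physical: nx.Graph
    functional: nx.Graph
    table: pd.DataFrame


def similarity_graphs(
    la_clusters: dict[str, tuple[str, ...]],
    ha_clusters: dict[str, tuple[str, ...]],
    enriched_terms: dict[str, list[str]],
    universe_size: int,
    wang: WangSimilarity | None = None,
    null_sample: np.ndarray | None = None,
    alpha: float = 0.05,
) -> SimilarityResult:
    """Physical and functional cluster-similarity graphs.

    Physical edges connect LA clusters to HA clusters whose gene overlap is
    hypergeometrically significant; clusters of the same partition never
    overlap, so within-phenotype physical tests are skipped. Functional
    edges connect any two GO-enriched clusters (within- or cross-phenotype)
    whose Wang+BMA similarity beats the empirical null at ``alpha``. The
    returned table lists every tested pair.
    """
    physical = nx.Graph(kind="physical")
    functional = nx.Graph(kind="functional")
    rows = []
    for la_id, la_genes in sorted(la_clusters.items()):
        for ha_id, ha_genes in sorted(ha_clusters.items()):
            k, p = hypergeom_overlap(la_genes, ha_genes, universe_size)
            rows.append(
                {
                    "cluster_a": la_id,
                    "cluster_b": ha_id,
                    "kind": "physical",
                    "statistic": k,
                    "p_value": p,
                }
            )
            if p < alpha:
                physical.add_edge(la_id, ha_id, overlap=k, p_value=p)
    enriched = {c: t for c, t in enriched_terms.items() if t}
    if enriched and (wang is None or null_sample is None):
        raise ValueError("functional similarity needs a Wang scorer and a null sample")
    ids = sorted(enriched)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sim = term_set_similarity(enriched[a], enriched[b], wang)
            p = empirical_pvalue(sim, null_sample)
            rows.append(
                {
                    "cluster_a": a,
                    "cluster_b": b,
                    "kind": "functional",
                    "statistic": sim,
                    "p_value": p,
                }
            )
            if p < alpha:
                functional.add_edge(a, b, similarity=sim, p_value=p)
    table = pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "kind", "statistic", "p_value"]
    )
    return SimilarityResult(physical=physical, functional=functional, table=table)
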