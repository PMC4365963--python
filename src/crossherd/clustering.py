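"""Map-equation consensus clustering with null-model significance.

Each network is partitioned by Infomap (the map-equation heuristic, via
igraph) wrapped in iterative consensus clustering: a batch of seeded runs is
reduced to a co-assignment frequency matrix, frequencies below ``tau`` are
zeroed, the matrix is re-clustered as a weighted graph, and the process
repeats until every run of an iteration returns the same partition.

Cluster quality is then assessed against degree-preserving null models:

* node inclusion: under the configuration model, the probability that a
  degree-k node places at least its observed number of edge endpoints inside
  the cluster is a hypergeometric tail over edge endpoints; members whose
  tail probability exceeds ``alpha_node`` are pruned;
* cluster significance: the total internal edge weight is compared with the
  same quantity in an ensemble of degree-preserving edge rewirings (edge
  weights shuffled with the edges), giving an add-one-corrected empirical
  p-value.

Clusters smaller than ``min_size`` or with p >= alpha are finally excluded.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .preprocess import PhenotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ScoredCluster",
    "ConvergenceError",
    "partition_once",
    "consensus_cluster",
    "node_inclusion_cleanup",
    "cluster_significance",
    "cluster_significance_batch",
    "filter_clusters",
    "summarize_cluster",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class Partition:
    """A hard partition of network nodes with its map-equation codelength."""

    membership: dict[str, int]
    seed: int
    codelength: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in out.items()}

    def canonical(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(nodes) for nodes in self.clusters().values())


@dataclass
class ScoredCluster:
    cluster_id: str
    genes: tuple[str, ...]
    p_value: float
    correlation_summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    weights = [float(d.get("weight", 1.0)) for _, _, d in net.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def partition_once(net: nx.Graph, seed: int) -> Partition:
    """One seeded Infomap run (two-level map equation)."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    g, nodes = _to_igraph(net)
    ig.set_random_number_generator(random.Random(seed))
    vc = g.community_infomap(edge_weights="weight" if g.ecount() else None, trials=1)
    membership = {node: int(cid) for node, cid in zip(nodes, vc.membership)}
    return Partition(membership=membership, seed=seed, codelength=float(vc.codelength))


def consensus_cluster(
    net: nx.Graph,
    runs_per_iter: int = 500,
    tau: float = 0.5,
    max_iter: int = 10,
    master_seed: int = 0,
) -> tuple[Partition, int]:
    """Iterative consensus clustering; returns the partition and iteration count.

    Run seeds are derived as ``master_seed + i`` with ``i`` counting across
    all iterations. Convergence means every run of the iteration produced
    the identical partition.
    """
    if runs_per_iter < 2:
        raise ValueError("runs_per_iter must be >= 2")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    current = net
    seed_counter = 0
    agreement = 0.0
    for iteration in range(1, max_iter + 1):
        parts = [
            partition_once(current, master_seed + seed_counter + i)
            for i in range(runs_per_iter)
        ]
        seed_counter += runs_per_iter
        canon = [p.canonical() for p in parts]
        agreement = max(canon.count(c) for c in set(canon)) / runs_per_iter
        if agreement == 1.0:
            final = parts[0]
            logger.info(
                "consensus converged after %d iteration(s), %d clusters",
                iteration,
                len(final.clusters()),
            )
            return final, iteration
        # co-assignment frequencies over this iteration's runs
        co = np.zeros((len(nodes), len(nodes)))
        for p in parts:
            labels = np.array([p.membership[n] for n in nodes])
            co += labels[:, None] == labels[None, :]
        co /= runs_per_iter
        co[co < tau] = 0.0
        consensus = nx.Graph(phenotype=net.graph.get("phenotype"))
        consensus.add_nodes_from(nodes)
        ii, jj = np.nonzero(np.triu(co, k=1))
        for a, b in zip(ii, jj):
            consensus.add_edge(nodes[a], nodes[b], weight=float(co[a, b]))
        current = consensus
    raise ConvergenceError(
        f"no consensus after {max_iter} iterations (last agreement {agreement:.3f})"
    )


def node_inclusion_cleanup(
    net: nx.Graph, cluster, alpha_node: float = 0.05
) -> list[str]:
    """Prune cluster members that the configuration model explains by chance.

    For member v with degree k_v and k_in within-cluster neighbours, the null
    probability that k_v edge endpoints drawn from the network's remaining
    endpoint stubs place >= k_in inside the cluster is a hypergeometric tail;
    v is dropped when that tail exceeds ``alpha_node``. The pass is repeated
    once on the pruned cluster.
    """
    members = set(cluster)
    if not members <= set(net.nodes):
        raise ValueError("cluster contains nodes absent from the network")
    two_m = 2 * net.number_of_edges()
    for _ in range(2):
        drops = []
        for v in sorted(members):
            k_v = net.degree(v)
            k_in = sum(1 for u in net.neighbors(v) if u in members and u != v)
            stubs_in = sum(net.degree(u) for u in members if u != v)
            population = two_m - k_v
            tail = hypergeom.sf(k_in - 1, population, min(stubs_in, population), k_v)
            if tail > alpha_node:
                drops.append(v)
        if not drops:
            break
        members -= set(drops)
    return sorted(members)


def _edge_arrays(net: nx.Graph) -> tuple[list[tuple[str, str]], np.ndarray]:
    edges = list(net.edges)
    weights = np.array(
        [float(net.edges[e].get("weight", 1.0)) for e in edges], dtype=float
    )
    return edges, weights


def _rewire_edges(
    edges: list[tuple[int, int]], rng: np.random.Generator, n_attempts: int
) -> list[tuple[int, int]]:
    """Degree-preserving double-edge swaps on an integer edge list."""
    edges = list(edges)
    m = len(edges)
    edge_set = {frozenset(e) for e in edges}
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    return edges


def cluster_significance_batch(
    net: nx.Graph,
    clusters: list,
    n_null: int = 999,
    seed: int = 0,
    swaps_per_edge: int = 4,
) -> list[float]:
    """Rewiring-ensemble significance for several disjoint clusters at once.

    The null ensemble (degree-preserving rewirings with edge weights shuffled
    with the edges) is generated once and every cluster is scored against
    each null graph by its internal edge-weight sum;
    ``p = (1 + #{null >= observed}) / (n_null + 1)``.
    """
    if n_null < 99:
        raise ValueError("n_null < 99 gives too coarse a p-value resolution")
    for c in clusters:
        if len(c) < 2:
            raise ValueError("cluster significance needs >= 2 members")
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edge_names, weights = _edge_arrays(net)
    edges = [(index[u], index[v]) for u, v in edge_names]
    label = np.full(len(nodes), -1, dtype=int)
    for ci, cluster in enumerate(clusters):
        for g in cluster:
            label[index[g]] = ci
    u = np.array([e[0] for e in edges])
    v = np.array([e[1] for e in edges])
    internal = (label[u] >= 0) & (label[u] == label[v])
    observed = np.zeros(len(clusters))
    np.add.at(observed, label[u[internal]], weights[internal])

    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * len(edges)
    exceed = np.zeros(len(clusters))
    for _ in range(n_null):
        null_edges = _rewire_edges(edges, rng, n_attempts)
        nu = np.array([e[0] for e in null_edges])
        nv = np.array([e[1] for e in null_edges])
        null_weights = rng.permutation(weights)
        null_internal = (label[nu] >= 0) & (label[nu] == label[nv])
        null_score = np.zeros(len(clusters))
        np.add.at(null_score, label[nu[null_internal]], null_weights[null_internal])
        exceed += null_score >= observed - 1e-12
    return list((1.0 + exceed) / (n_null + 1.0))


def cluster_significance(
    net: nx.Graph, cluster, n_null: int = 999, seed: int = 0
) -> float:
    """Rewiring-ensemble p-value for one cluster's internal edge weight."""
    return cluster_significance_batch(net, [list(cluster)], n_null=n_null, seed=seed)[0]


def filter_clusters(
    clusters: list[ScoredCluster], min_size: int = 10, alpha: float = 0.05
) -> list[ScoredCluster]:
    """Keep clusters with size >= min_size AND p < alpha."""
    return [c for c in clusters if c.size >= min_size and c.p_value < alpha]


def summarize_cluster(
    cluster, pset: PhenotypeSet
) -> dict[str, tuple[float, float]]:
    """Per-dataset mean and sd of within-cluster pairwise correlations."""
    genes = sorted(cluster)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes to summarise")
    out: dict[str, tuple[float, float]] = {}
    for m in pset.matrices:
        sub = m.values.loc[genes].to_numpy(dtype=float)
        corr = np.corrcoef(sub)
        iu = np.triu_indices(len(genes), k=1)
        vals = corr[iu]
        out[m.dataset_id] = (float(np.mean(vals)), float(np.std(vals)))
    return out
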