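"""Consensus map-equation clustering and null-model cluster statistics."""

import networkx as nx
import numpy as np
import pytest

from crossherd.clustering import (
    ScoredCluster,
    _rewire_edges,
    cluster_significance,
    consensus_cluster,
    filter_clusters,
    node_inclusion_cleanup,
    partition_once,
    summarize_cluster,
)
from crossherd.preprocess import PhenotypeSet
from conftest import make_matrix


def two_cliques(k=5):
    g = nx.Graph()
    for offset, prefix in ((0, "a"), (k, "b")):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(f"{prefix}{i}", f"{prefix}{j}", weight=1.0)
    return g


def planted_modules_graph(n_modules=3, size=30, p_in=1.0, p_out=0.01, seed=0):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n_modules * size)]
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            same = i // size == j // size
            if rng.random() < (p_in if same else p_out):
                g.add_edge(nodes[i], nodes[j], weight=1.0 if same else 0.2)
    return g, {n: i // size for i, n in enumerate(nodes)}


class TestPartitionOnce:
    def test_disconnected_cliques_found(self):
        part = partition_once(two_cliques(), seed=1)
        clusters = part.canonical()
        assert clusters == frozenset(
            {
                frozenset(f"a{i}" for i in range(5)),
                frozenset(f"b{i}" for i in range(5)),
            }
        )

    def test_single_edge_degenerate(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        part = partition_once(g, seed=0)
        assert len(part.clusters()) in (1, 2)

    def test_seed_determinism(self):
        g, _ = planted_modules_graph(seed=5)
        a = partition_once(g, seed=11)
        b = partition_once(g, seed=11)
        assert a.membership == b.membership
        assert a.codelength == b.codelength

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            partition_once(nx.Graph(), seed=0)


class TestConsensus:
    def test_cliques_converge_first_iteration(self):
        part, iterations = consensus_cluster(
            two_cliques(), runs_per_iter=10, master_seed=0
        )
        assert iterations == 1
        assert len(part.clusters()) == 2

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            g, truth = planted_modules_graph(seed=seed, p_in=0.9, p_out=0.03)
            part, _ = consensus_cluster(g, runs_per_iter=20, master_seed=seed)
            nodes = sorted(truth)
            ari = adjusted_rand_score(
                [truth[n] for n in nodes], [part.membership[n] for n in nodes]
            )
            assert ari >= 0.8

    def test_idempotent_on_converged_output(self):
        g, _ = planted_modules_graph(seed=2, p_in=0.9, p_out=0.02)
        part, _ = consensus_cluster(g, runs_per_iter=20, master_seed=3)
        again, iterations = consensus_cluster(g, runs_per_iter=20, master_seed=3)
        assert again.canonical() == part.canonical()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            consensus_cluster(two_cliques(), runs_per_iter=1)
        with pytest.raises(ValueError):
            consensus_cluster(two_cliques(), tau=1.5)


class TestNodeCleanup:
    def test_clique_members_retained(self):
        g = two_cliques()
        cluster = [f"a{i}" for i in range(5)]
        assert node_inclusion_cleanup(g, cluster, alpha_node=0.05) == sorted(cluster)

    def test_detached_node_dropped(self):
        g = two_cliques(8)
        cluster = [f"a{i}" for i in range(8)] + ["b0"]  # b0 has no edge into the a-clique
        kept = node_inclusion_cleanup(g, cluster, alpha_node=0.05)
        assert "b0" not in kept
        assert set(kept) == {f"a{i}" for i in range(8)}

    def test_spuriously_attached_node_dropped(self):
        rng = np.random.default_rng(1)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                g.add_edge(clique[i], clique[j], weight=1.0)
        # sparse background of 200 extra nodes
        extra = [f"x{i}" for i in range(200)]
        for _ in range(400):
            u, v = rng.choice(200, size=2, replace=False)
            g.add_edge(extra[u], extra[v], weight=1.0)
        # the spurious node touches the clique once but mostly lives outside
        g.add_edge("spur", clique[0], weight=1.0)
        for i in range(9):
            g.add_edge("spur", extra[i], weight=1.0)
        kept = node_inclusion_cleanup(g, clique + ["spur"], alpha_node=0.05)
        assert "spur" not in kept
        assert set(kept) == set(clique)

    def test_unknown_node_errors(self):
        with pytest.raises(ValueError):
            node_inclusion_cleanup(two_cliques(), ["a0", "zz"])


class TestSignificance:
    def test_rewiring_preserves_degrees(self):
        g, _ = planted_modules_graph(seed=4, p_in=0.7, p_out=0.05)
        nodes = list(g.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges]
        rng = np.random.default_rng(0)
        rewired = _rewire_edges(edges, rng, n_attempts=4 * len(edges))
        before = np.zeros(len(nodes), dtype=int)
        after = np.zeros(len(nodes), dtype=int)
        for u, v in edges:
            before[u] += 1
            before[v] += 1
        for u, v in rewired:
            after[u] += 1
            after[v] += 1
        assert np.array_equal(before, after)
        assert rewired != edges  # something actually moved
        assert len({frozenset(e) for e in rewired}) == len(rewired)  # simple graph

    def test_whole_network_cluster_p_is_one(self):
        g, _ = planted_modules_graph(seed=6, p_in=0.8, p_out=0.1)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        p = cluster_significance(g, list(g.nodes), n_null=99, seed=0)
        assert p == pytest.approx(1.0)

    def test_planted_clique_significant(self):
        rng = np.random.default_rng(2)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                g.add_edge(clique[i], clique[j], weight=1.0)
        extra = [f"x{i}" for i in range(90)]
        for _ in range(200):
            u, v = rng.choice(90, size=2, replace=False)
            g.add_edge(extra[u], extra[v], weight=1.0)
        p = cluster_significance(g, clique, n_null=199, seed=0)
        assert p <= 0.05

    def test_coarse_null_count_rejected(self):
        with pytest.raises(ValueError):
            cluster_significance(two_cliques(), ["a0", "a1"], n_null=50)


class TestFilterAndSummary:
    def test_boundary_semantics(self):
        clusters = [
            ScoredCluster("keep", tuple(f"g{i}" for i in range(11)), 0.04384),
            ScoredCluster("small", tuple(f"g{i}" for i in range(9)), 0.001),
            ScoredCluster("weak", tuple(f"g{i}" for i in range(50)), 0.05),
        ]
        kept = filter_clusters(clusters, min_size=10, alpha=0.05)
        assert [c.cluster_id for c in kept] == ["keep"]

    def test_two_gene_cluster_summary(self):
        m = make_matrix([[1.0, 2, 3, 5], [1, 2, 3, 4]], dataset_id="d1")
        m2 = make_matrix([[1.0, 2, 3, 5], [-1, -2, -3, -4]], dataset_id="d2")
        pset = PhenotypeSet("LA", [m, m2])
        summary = summarize_cluster(["g0", "g1"], pset)
        r1 = np.corrcoef(m.values.to_numpy())[0, 1]
        assert summary["d1"][0] == pytest.approx(r1)
        assert summary["d1"][1] == pytest.approx(0.0)
        assert summary["d2"][0] < 0

    def test_uncorrelated_cluster_mean_near_zero(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(20, 200)))
        pset = PhenotypeSet("LA", [m, make_matrix(rng.normal(size=(20, 200)),
                                                  dataset_id="d2")])
        summary = summarize_cluster([f"g{i}" for i in range(20)], pset)
        for mean, _ in summary.values():
            assert abs(mean) < 0.05
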