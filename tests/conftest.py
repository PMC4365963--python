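import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crossherd.io_formats import ExpressionMatrix, OntologyGraph

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_matrix(
    values,
    gene_ids=None,
    sample_ids=None,
    dataset_id="ds1",
    platform="intensity",
    phenotype="LA",
) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        dataset_id, platform, phenotype, pd.DataFrame(arr, index=genes, columns=samples)
    )


@pytest.fixture
def toy_dag() -> OntologyGraph:
    """Hand-built BP DAG: root with two branches, one part_of edge.

        GO:0000001 (root)
        |- GO:0000002 (A, is_a)        |- GO:0000005 (D, is_a)
           |- GO:0000003 (B, is_a A)      |- GO:0000006 (E, is_a D)
           |- GO:0000004 (C, part_of A)
    """
    g = nx.DiGraph()
    edges = [
        ("GO:0000002", "GO:0000001", "is_a"),
        ("GO:0000003", "GO:0000002", "is_a"),
        ("GO:0000004", "GO:0000002", "part_of"),
        ("GO:0000005", "GO:0000001", "is_a"),
        ("GO:0000006", "GO:0000005", "is_a"),
    ]
    g.add_node("GO:0000001")
    for child, parent, rel in edges:
        g.add_edge(child, parent, relation=rel)
    terms = sorted(g.nodes)
    return OntologyGraph(
        graph=g,
        names={t: f"term {t[-1]}" for t in terms},
        namespaces={t: "biological_process" for t in terms},
    )


@pytest.fixture
def random_weighted_network() -> nx.Graph:
    """A 50-edge random network with the co-expression edge attributes."""
    rng = np.random.default_rng(7)
    net = nx.Graph(phenotype="LA")
    edges = set()
    while len(edges) < 50:
        u, v = rng.integers(0, 25, size=2)
        if u != v:
            edges.add((f"g{min(u, v)}", f"g{max(u, v)}"))
    for u, v in sorted(edges):
        net.add_edge(
            u,
            v,
            cor_DuF2=float(rng.uniform(0.5, 1)),
            cor_Duroc=float(rng.uniform(0.5, 1)),
            cor_Landrace=float(rng.uniform(0.5, 1)),
            joint_cdf=float(rng.uniform(0, 1)),
        )
    return net
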