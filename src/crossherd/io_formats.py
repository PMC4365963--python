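"""Readers and writers for every external representation the pipeline touches.

Expression matrices travel as tab-separated text (first column: gene or probe
identifier, header row: sample identifiers). Networks are exported as GraphML
(default) or XGMML (for Cytoscape); both round-trip node sets, edge sets and
numeric edge attributes. Gene Ontology structure is parsed from OBO 1.2 text,
keeping only ``is_a`` and ``part_of`` relationships, dropping obsolete terms
and aliasing ``alt_id`` entries to their primary term.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("count", "intensity")
PHENOTYPES = ("LA", "HA")

#: GO relationship types consumed by the ontology graph, with the edge weights
#: used later by the Wang semantic-similarity measure.
ONTOLOGY_RELATIONS = ("is_a", "part_of")


class LoadError(ValueError):
    """Raised when an external file violates a format contract."""


class ExportError(ValueError):
    """Raised when an object cannot be serialised (e.g. missing attributes)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric table with provenance labels.

    ``platform`` distinguishes count-valued RNA-seq-like data (non-negative
    integers) from continuous microarray-like intensities. ``phenotype`` is
    the androstenone group label (LA = low, HA = high).
    """

    dataset_id: str
    platform: str
    phenotype: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise LoadError(f"duplicate gene id {dup!r} in dataset {self.dataset_id!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise LoadError(f"duplicate sample id {dup!r} in dataset {self.dataset_id!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise LoadError(f"non-numeric values in dataset {self.dataset_id!r}")
        if np.isnan(arr.astype(float)).any():
            row = idx[np.isnan(arr.astype(float)).any(axis=1)][0]
            raise LoadError(f"missing value in row {row!r} of dataset {self.dataset_id!r}")
        if self.platform == "count":
            if (arr < 0).any():
                raise LoadError(f"negative count in dataset {self.dataset_id!r}")
            if not np.allclose(arr, np.round(arr)):
                raise LoadError(f"non-integer count in dataset {self.dataset_id!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, platform: str | None = None) -> "ExpressionMatrix":
        """Return a copy carrying the same labels but new values."""
        return ExpressionMatrix(
            dataset_id=self.dataset_id,
            platform=self.platform if platform is None else platform,
            phenotype=self.phenotype,
            values=values,
        )


@dataclass(frozen=True)
class ProbeMap:
    """Many-to-one mapping from platform probe ids to gene ids."""

    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.probe_to_gene:
            raise ValueError("empty probe map")

    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())


@dataclass
class AnnotationTable:
    """gene id -> set of term ids (GO terms or pathway ids) with a namespace tag."""

    gene_to_terms: dict[str, frozenset[str]]
    namespace: str = ""

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_to_terms.values():
            out |= t
        return out

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        inv: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(g)
        return {t: frozenset(gs) for t, gs in inv.items()}

    def restrict_genes(self, genes: Iterable[str]) -> "AnnotationTable":
        keep = set(genes)
        return AnnotationTable(
            {g: t for g, t in self.gene_to_terms.items() if g in keep}, self.namespace
        )


@dataclass
class OntologyGraph:
    """A GO-style DAG: directed edges point term -> parent with a typed relation.

    Only ``is_a`` and ``part_of`` edges are stored. ``alt_ids`` maps retired
    alternative identifiers onto their primary term.
    """

    graph: nx.DiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise LoadError("ontology graph contains a cycle")

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def resolve(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """Typed parent edges of *term* as (parent, relation) pairs."""
        t = self.resolve(term)
        return [(p, self.graph.edges[t, p]["relation"]) for p in self.graph.successors(t)]

    def children(self, term: str) -> list[tuple[str, str]]:
        t = self.resolve(term)
        return [(c, self.graph.edges[c, t]["relation"]) for c in self.graph.predecessors(t)]

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        t = self.resolve(term)
        anc = nx.descendants(self.graph, t)  # edges point towards parents
        if include_self:
            anc.add(t)
        return anc

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.graph.nodes)
        return [n for n in self.graph.nodes if self.namespaces.get(n) == namespace]


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, dataset_id: str, platform: str, phenotype: str
) -> ExpressionMatrix:
    """Load a tab-separated expression table (rows: genes/probes, cols: samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise LoadError(f"{path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        raise LoadError(f"{path}: non-numeric cell in row {row!r}")
    if numeric.isna().to_numpy().any():
        row = numeric.index[numeric.isna().any(axis=1)][0]
        raise LoadError(f"{path}: missing value in row {row!r}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(dataset_id, platform, phenotype, numeric)


def write_expression(m: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a two-column probe_id<TAB>gene_id table (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: probe map needs two columns")
    if list(df.columns[:2]) != ["probe_id", "gene_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise LoadError(f"{path}: probe {dup!r} mapped more than once")
    return ProbeMap(dict(zip(probes, genes)))


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _required_edge_attrs(net: nx.Graph) -> list[str]:
    """Validate edge attributes and return the ordered attribute names."""
    keys: set[str] | None = None
    for _, _, data in net.edges(data=True):
        if "joint_cdf" not in data:
            raise ExportError("edge missing required attribute 'joint_cdf'")
        cors = {k for k in data if k.startswith("cor_")}
        if not cors:
            raise ExportError("edge missing per-dataset correlation attributes (cor_*)")
        if keys is None:
            keys = cors
        elif keys != cors:
            raise ExportError("inconsistent per-dataset correlation attributes across edges")
    return sorted(keys or set()) + ["joint_cdf"]


def write_network(net: nx.Graph, path: str | Path, dialect: str = "graphml") -> Path:
    """Export a co-expression network with its per-dataset correlation attributes."""
    path = Path(path)
    attrs = _required_edge_attrs(net)
    if dialect == "graphml":
        out = nx.Graph()
        out.graph.update({k: v for k, v in net.graph.items() if v is not None})
        out.add_nodes_from(net.nodes)
        for u, v, data in net.edges(data=True):
            out.add_edge(u, v, **{k: float(data[k]) for k in attrs})
        nx.write_graphml(out, path)
    elif dialect == "xgmml":
        _write_xgmml(net, path, attrs)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _write_xgmml(net: nx.Graph, path: Path, attrs: list[str]) -> None:
    root = ET.Element(
        "graph",
        {
            "label": str(net.graph.get("phenotype", "network")),
            "directed": "0",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    ids = {n: str(i) for i, n in enumerate(net.nodes)}
    for n, i in ids.items():
        ET.SubElement(root, "node", {"id": i, "label": str(n)})
    for u, v, data in net.edges(data=True):
        e = ET.SubElement(root, "edge", {"source": ids[u], "target": ids[v]})
        for k in attrs:
            ET.SubElement(
                e, "att", {"name": k, "value": repr(float(data[k])), "type": "real"}
            )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_network(path: str | Path, dialect: str = "graphml") -> nx.Graph:
    path = Path(path)
    if dialect == "graphml":
        g = nx.read_graphml(path, node_type=str)
        out = nx.Graph()
        out.graph.update(g.graph)
        out.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, **{k: float(x) for k, x in data.items() if k != "id"})
        return out
    if dialect == "xgmml":
        return _read_xgmml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_xgmml(path: Path) -> nx.Graph:
    tree = ET.parse(path)
    root = tree.getroot()
    ns = {"x": "http://www.cs.rpi.edu/XGMML"}
    g = nx.Graph(phenotype=root.get("label"))
    labels: dict[str, str] = {}
    for node in root.findall("x:node", ns):
        labels[node.get("id")] = node.get("label")
        g.add_node(node.get("label"))
    for edge in root.findall("x:edge", ns):
        u, v = labels[edge.get("source")], labels[edge.get("target")]
        data = {
            att.get("name"): float(att.get("value")) for att in edge.findall("x:att", ns)
        }
        g.add_edge(u, v, **data)
    return g


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 ontology, keeping is_a / part_of edges only.

    Obsolete terms are dropped (obonet's default); other relationship types
    are ignored with a logged warning; alt_id entries are aliased to their
    primary term. Raises :class:`LoadError` if the result is not acyclic.
    """
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        g.add_node(term)
        if "name" in data:
            names[term] = data["name"]
        if "namespace" in data:
            namespaces[term] = data["namespace"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    dropped: set[str] = set()
    for child, parent, rel in multi.edges(keys=True):
        if rel in ONTOLOGY_RELATIONS:
            g.add_edge(child, parent, relation=rel)
        else:
            dropped.add(rel)
    if dropped:
        logger.warning("ignored ontology relationship types: %s", sorted(dropped))
    return OntologyGraph(graph=g, alt_ids=alt_ids, names=names, namespaces=namespaces)


def write_obo(onto: OntologyGraph, path: str | Path) -> Path:
    """Write a minimal OBO 1.2 serialisation (used for fixtures and exports)."""
    path = Path(path)
    lines = ["format-version: 1.2", ""]
    for term in sorted(onto.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {onto.names.get(term, term)}")
        if term in onto.namespaces:
            lines.append(f"namespace: {onto.namespaces[term]}")
        for alt, primary in sorted(onto.alt_ids.items()):
            if primary == term:
                lines.append(f"alt_id: {alt}")
        for parent, rel in sorted(onto.parents(term)):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def read_annotations(path: str | Path, namespace: str = "") -> AnnotationTable:
    """Read a two-column gene_id<TAB>term_id annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    gene_to_terms: dict[str, set[str]] = {}
    for g, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene_to_terms.setdefault(g, set()).add(t)
    return AnnotationTable({g: frozenset(t) for g, t in gene_to_terms.items()}, namespace)


def write_annotations(ann: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(ann.gene_to_terms)
        for t in sorted(ann.gene_to_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Cluster tables
# ---------------------------------------------------------------------------

def write_clusters(clusters, path: str | Path) -> Path:
    """Write cluster membership as TSV: cluster_id, gene_id, p_value."""
    path = Path(path)
    rows = []
    for c in clusters:
        for g in c.genes:
            rows.append({"cluster_id": c.cluster_id, "gene_id": g, "p_value": c.p_value})
    pd.DataFrame(rows, columns=["cluster_id", "gene_id", "p_value"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_clusters(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "gene_id": str})
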