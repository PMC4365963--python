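"""End-to-end orchestration: preprocess -> networks -> clusters -> enrichment
-> cluster similarity, for both phenotype groups, from a single config.

The run is fully deterministic given the config (including its master seed);
a manifest records seeds and the counts at every stage so conservation
invariants (retained pairs <= computed pairs, clustered genes <= network
nodes <= common genes) can be asserted downstream. A leave-one-dataset-out
sanity check reruns a phenotype without one dataset and compares the
resulting significant clusters to the full run by hypergeometric overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import clustering, coexpression, enrichment, similarity
from .io_formats import (
    AnnotationTable,
    ExpressionMatrix,
    OntologyGraph,
    read_annotations,
    read_expression,
    read_obo,
    write_clusters,
    write_network,
)
from .preprocess import PhenotypeSet, group_by_phenotype, intersect_genes, log_cpm

logger = logging.getLogger(__name__)

__all__ = ["DatasetDecl", "RunConfig", "PhenotypeResult", "run_phenotype", "run_full", "sanity_check"]


@dataclass(frozen=True)
class DatasetDecl:
    dataset_id: str
    platform: str
    phenotype: str
    path: str | None = None


@dataclass
class RunConfig:
    """All thresholds and inputs of a full analysis run.

    ``datasets`` may be file declarations or in-memory
    :class:`ExpressionMatrix` objects (e.g. from the synthetic generator).
    """

    datasets: list = field(default_factory=list)
    correlation_threshold: float = 0.5
    cluster_alpha: float = 0.05
    min_cluster_size: int = 10
    alpha_node: float = 0.05
    enrichment_alpha: float = 0.05
    min_annotated_genes: int = 5
    elim_alpha: float = 0.01
    similarity_alpha: float = 0.05
    runs_per_iter: int = 500
    tau: float = 0.5
    max_iter: int = 10
    n_null: int = 999
    null_similarity_draws: int = 10_000
    prior_count: float = 0.5
    master_seed: int = 42
    obo_path: str | None = None
    go_annotation_path: str | None = None
    pathway_annotation_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("cluster_alpha", "enrichment_alpha", "similarity_alpha", "tau"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not -1.0 <= self.correlation_threshold < 1.0:
            raise ValueError("correlation_threshold out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        decls = [DatasetDecl(**d) for d in raw.pop("datasets", [])]
        return cls(datasets=decls, **raw)


@dataclass
class PhenotypeResult:
    phenotype: str
    network: nx.Graph
    iterations: int
    clusters: list
    significant: list
    go_results: dict
    pathway_results: dict
    manifest: dict
    phenotype_set: PhenotypeSet


def _load_matrices(config: RunConfig) -> list[ExpressionMatrix]:
    out = []
    for d in config.datasets:
        if isinstance(d, ExpressionMatrix):
            out.append(d)
        else:
            if d.path is None:
                raise ValueError(f"dataset {d.dataset_id}: no path given")
            out.append(read_expression(d.path, d.dataset_id, d.platform, d.phenotype))
    return out


def _preprocess(config: RunConfig) -> tuple[PhenotypeSet, PhenotypeSet]:
    matrices = _load_matrices(config)
    matrices = [
        log_cpm(m, config.prior_count) if m.platform == "count" else m
        for m in matrices
    ]
    matrices = intersect_genes(matrices)
    return group_by_phenotype(matrices)


def _load_annotations(
    config: RunConfig,
) -> tuple[OntologyGraph | None, AnnotationTable | None, AnnotationTable | None]:
    onto = read_obo(config.obo_path) if config.obo_path else None
    go_ann = (
        read_annotations(config.go_annotation_path, "biological_process")
        if config.go_annotation_path
        else None
    )
    pw_ann = (
        read_annotations(config.pathway_annotation_path, "pathway")
        if config.pathway_annotation_path
        else None
    )
    return onto, go_ann, pw_ann


def run_phenotype(
    config: RunConfig,
    phenotype: str,
    *,
    phenotype_sets: tuple[PhenotypeSet, PhenotypeSet] | None = None,
    onto: OntologyGraph | None = None,
    go_ann: AnnotationTable | None = None,
    pathway_ann: AnnotationTable | None = None,
) -> PhenotypeResult:
    """Execute preprocess -> network -> clustering -> enrichment for one group."""
    if phenotype_sets is None:
        phenotype_sets = _preprocess(config)
    pset = phenotype_sets[0] if phenotype == "LA" else phenotype_sets[1]
    if onto is None and go_ann is None and pathway_ann is None:
        onto, go_ann, pathway_ann = _load_annotations(config)
    manifest: dict = {
        "phenotype": phenotype,
        "master_seed": config.master_seed,
        "datasets": pset.dataset_ids,
        "common_genes": len(pset.gene_ids),
    }

    net, counts = coexpression.phenotype_network(
        pset, threshold=config.correlation_threshold
    )
    manifest.update(counts)

    scored: list[clustering.ScoredCluster] = []
    significant: list[clustering.ScoredCluster] = []
    iterations = 0
    if net.number_of_edges() > 0:
        partition, iterations = clustering.consensus_cluster(
            net,
            runs_per_iter=config.runs_per_iter,
            tau=config.tau,
            max_iter=config.max_iter,
            master_seed=config.master_seed,
        )
        raw_clusters = [
            members
            for _, members in sorted(partition.clusters().items())
        ]
        cleaned = [
            clustering.node_inclusion_cleanup(net, c, alpha_node=config.alpha_node)
            for c in raw_clusters
        ]
        cleaned = [c for c in cleaned if len(c) >= 2]
        pvals = clustering.cluster_significance_batch(
            net, cleaned, n_null=config.n_null, seed=config.master_seed + 1_000_000
        )
        for i, (members, p) in enumerate(zip(cleaned, pvals)):
            scored.append(
                clustering.ScoredCluster(
                    cluster_id=f"{phenotype} {i}",
                    genes=tuple(members),
                    p_value=p,
                    correlation_summary=clustering.summarize_cluster(members, pset),
                )
            )
        significant = clustering.filter_clusters(
            scored, min_size=config.min_cluster_size, alpha=config.cluster_alpha
        )
    manifest["iterations"] = iterations
    manifest["clusters"] = len(scored)
    manifest["significant_clusters"] = len(significant)
    manifest["clustered_genes"] = sum(c.size for c in scored)

    go_results: dict = {}
    pathway_results: dict = {}
    background = pset.gene_ids
    for c in significant:
        if onto is not None and go_ann is not None:
            go_results[c.cluster_id] = enrichment.go_enrich(
                c.genes,
                background,
                onto,
                go_ann,
                algorithm="elim",
                elim_alpha=config.elim_alpha,
                alpha=config.enrichment_alpha,
                min_genes=config.min_annotated_genes,
            )
        if pathway_ann is not None:
            pathway_results[c.cluster_id] = enrichment.pathway_enrich(
                c.genes,
                background,
                pathway_ann,
                alpha=config.enrichment_alpha,
                min_genes=config.min_annotated_genes,
            )

    result = PhenotypeResult(
        phenotype=phenotype,
        network=net,
        iterations=iterations,
        clusters=scored,
        significant=significant,
        go_results=go_results,
        pathway_results=pathway_results,
        manifest=manifest,
        phenotype_set=pset,
    )
    if config.out_dir:
        _write_phenotype_outputs(result, config)
    return result


def _write_phenotype_outputs(result: PhenotypeResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.network.number_of_edges() > 0:
        write_network(result.network, out / f"{result.phenotype}_network.graphml")
    write_clusters(result.significant, out / f"{result.phenotype}_clusters.tsv")
    (out / f"{result.phenotype}_manifest.json").write_text(
        json.dumps(result.manifest, indent=2)
    )
    for cid, results in {**result.go_results, **result.pathway_results}.items():
        rows = [
            {
                "term_id": r.term_id,
                "name": r.term_name,
                "n_genes": r.n_enriched_genes,
                "p_value": r.p_value,
                "genes": ",".join(r.genes),
            }
            for r in results
        ]
        safe = cid.replace(" ", "_")
        pd.DataFrame(rows, columns=["term_id", "name", "n_genes", "p_value", "genes"]).to_csv(
            out / f"enrichment_{safe}.tsv", sep="\t", index=False
        )


@dataclass
class FullResult:
    la: PhenotypeResult
    ha: PhenotypeResult
    similarity: similarity.SimilarityResult | None
    manifest: dict


def run_full(config: RunConfig) -> FullResult:
    """Both phenotypes plus physical/functional cluster similarity."""
    psets = _preprocess(config)
    onto, go_ann, pw_ann = _load_annotations(config)
    la = run_phenotype(
        config, "LA", phenotype_sets=psets, onto=onto, go_ann=go_ann, pathway_ann=pw_ann
    )
    ha = run_phenotype(
        config, "HA", phenotype_sets=psets, onto=onto, go_ann=go_ann, pathway_ann=pw_ann
    )
    sim_result = None
    la_clusters = {c.cluster_id: c.genes for c in la.significant}
    ha_clusters = {c.cluster_id: c.genes for c in ha.significant}
    if la_clusters and ha_clusters:
        enriched_terms = {
            cid: [r.term_id for r in res]
            for cid, res in {**la.go_results, **ha.go_results}.items()
        }
        wang = null = None
        if onto is not None and any(enriched_terms.values()):
            wang = similarity.WangSimilarity(onto)
            pool = sorted(
                {t for terms in (go_ann.gene_to_terms.values() if go_ann else []) for t in terms}
            )
            sizes = [len(t) for t in enriched_terms.values() if t]
            null = similarity.sample_null(
                pool,
                sizes,
                n_draws=config.null_similarity_draws,
                seed=config.master_seed + 2_000_000,
                wang=wang,
            )
        else:
            enriched_terms = {}
        sim_result = similarity.similarity_graphs(
            la_clusters,
            ha_clusters,
            enriched_terms,
            universe_size=len(la.phenotype_set.gene_ids),
            wang=wang,
            null_sample=null,
            alpha=config.similarity_alpha,
        )
    manifest = {
        "LA": la.manifest,
        "HA": ha.manifest,
        "similarity_pairs_tested": 0 if sim_result is None else int(len(sim_result.table)),
    }
    if config.out_dir and sim_result is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim_result.table.to_csv(out / "similarity_pairs.tsv", sep="\t", index=False)
        nx.write_graphml(sim_result.physical, out / "physical_similarity.graphml")
        nx.write_graphml(sim_result.functional, out / "functional_similarity.graphml")
    if config.out_dir:
        Path(config.out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2))
    return FullResult(la=la, ha=ha, similarity=sim_result, manifest=manifest)


def sanity_check(
    config: RunConfig,
    excluded_dataset_id: str,
    phenotype: str = "LA",
    full_result: PhenotypeResult | None = None,
) -> pd.DataFrame:
    """Leave-one-dataset-out rerun, compared to the full run cluster-by-cluster.

    Returns a table with one row per (full cluster, reduced cluster) pair
    whose hypergeometric overlap is significant: cluster ids, sizes, common
    gene count and p-value.
    """
    ids = [
        d.dataset_id if not isinstance(d, ExpressionMatrix) else d.dataset_id
        for d in config.datasets
    ]
    if excluded_dataset_id not in ids:
        raise ValueError(f"dataset {excluded_dataset_id!r} not in config")
    kept = [
        d
        for d in config.datasets
        if (d.dataset_id if isinstance(d, ExpressionMatrix) else d.dataset_id)
        != excluded_dataset_id
    ]
    reduced_config = RunConfig(**{**_config_dict(config), "datasets": kept, "out_dir": None})
    if full_result is None:
        full_result = run_phenotype(config, phenotype)
    reduced = run_phenotype(reduced_config, phenotype)
    universe = len(full_result.phenotype_set.gene_ids)
    rows = []
    for c_full in full_result.significant:
        for c_red in reduced.significant:
            k, p = similarity.hypergeom_overlap(c_full.genes, c_red.genes, universe)
            if p < config.similarity_alpha and k > 0:
                rows.append(
                    {
                        "cluster_full": c_full.cluster_id,
                        "cluster_reduced": c_red.cluster_id,
                        "size_full": c_full.size,
                        "size_reduced": c_red.size,
                        "common_genes": k,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_full",
            "cluster_reduced",
            "size_full",
            "size_reduced",
            "common_genes",
            "p_value",
        ],
    )


def _config_dict(config: RunConfig) -> dict:
    d = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    return d
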