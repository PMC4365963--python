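"""Synthetic multi-population expression data with planted co-expression modules.

The generator emulates the study layout this package targets: several
populations ("datasets") each measured in two phenotype groups (LA/HA, low
and high androstenone), with one count-valued RNA-seq-like platform and
Gaussian microarray-like platforms. Co-expressed modules are planted through
a shared per-sample latent factor:

* intensity platform: ``value = baseline + sd * (sqrt(rho)*z + sqrt(1-rho)*eps)``
  so the expected pairwise Pearson correlation of two module genes is ``rho``;
* count platform: negative-binomial counts whose natural-log mean is
  ``b + beta*z`` with ``beta = sqrt(v * rho/(1-rho))`` where
  ``v = dispersion + exp(-b)`` is the delta-method variance of the log count
  around its mean — so correlations after a log transform land near ``rho``.

Each dataset draws from its own RNG stream spawned from the master seed, so
adding a dataset never perturbs the data of earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    PHENOTYPES,
    PLATFORMS,
    AnnotationTable,
    ExpressionMatrix,
    OntologyGraph,
)

__all__ = [
    "ModuleSpec",
    "DatasetSpec",
    "SyntheticDesign",
    "generate",
    "generate_ontology_fixture",
    "example_design",
    "gene_id",
]


def gene_id(i: int) -> str:
    return f"G{i:05d}"


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``member_genes`` are integer gene indices into the design's gene universe;
    ``present_in_phenotype`` restricts the shared latent factor to one
    phenotype group ("LA" or "HA") or plants it in "both".
    """

    module_id: str
    member_genes: tuple[int, ...]
    within_correlation: float
    present_in_phenotype: str = "both"

    def __post_init__(self) -> None:
        if not 0.0 < self.within_correlation < 1.0:
            raise ValueError("within_correlation must lie strictly in (0, 1)")
        if self.present_in_phenotype not in (*PHENOTYPES, "both"):
            raise ValueError(f"bad phenotype {self.present_in_phenotype!r}")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise ValueError(f"module {self.module_id}: duplicate member genes")

    def active_in(self, phenotype: str) -> bool:
        return self.present_in_phenotype in ("both", phenotype)


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    platform: str
    n_samples: dict[str, int] = field(default_factory=lambda: {"LA": 20, "HA": 20})

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")


@dataclass(frozen=True)
class SyntheticDesign:
    n_genes: int
    datasets: tuple[DatasetSpec, ...]
    modules: tuple[ModuleSpec, ...]
    nb_dispersion: float = 0.1
    intensity_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.intensity_noise_sd <= 0:
            raise ValueError("intensity_noise_sd must be > 0")
        seen: set[int] = set()
        for m in self.modules:
            if max(m.member_genes, default=-1) >= self.n_genes or min(
                m.member_genes, default=0
            ) < 0:
                raise ValueError(f"module {m.module_id}: gene index out of range")
            overlap = seen & set(m.member_genes)
            if overlap:
                raise ValueError(f"module gene sets overlap at indices {sorted(overlap)[:3]}")
            seen |= set(m.member_genes)
        for d in self.datasets:
            for ph in PHENOTYPES:
                if d.n_samples.get(ph, 0) < 3:
                    raise ValueError(
                        f"dataset {d.dataset_id}: need >=3 samples per phenotype"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return [gene_id(i) for i in range(self.n_genes)]


def _intensity_dataset(
    design: SyntheticDesign, ds: DatasetSpec, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Gaussian platform: baseline + latent-mixed noise per phenotype group."""
    sd = design.intensity_noise_sd
    baseline = rng.normal(8.0, 1.0, size=design.n_genes)
    out = {}
    for ph in PHENOTYPES:
        n = ds.n_samples[ph]
        noise = rng.normal(size=(design.n_genes, n))
        values = baseline[:, None] + sd * noise
        for mod in design.modules:
            z = rng.normal(size=n)
            if not mod.active_in(ph):
                continue  # latent drawn regardless, keeping streams aligned
            rho = mod.within_correlation
            idx = np.array(mod.member_genes)
            values[idx] = baseline[idx, None] + sd * (
                np.sqrt(rho) * z[None, :] + np.sqrt(1.0 - rho) * noise[idx]
            )
        cols = [f"{ds.dataset_id}_{ph}_s{i}" for i in range(n)]
        out[ph] = pd.DataFrame(values, index=design.gene_ids, columns=cols)
    return out


def _count_dataset(
    design: SyntheticDesign, ds: DatasetSpec, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Negative-binomial platform with latent factor on the log-mean scale."""
    alpha = design.nb_dispersion
    log_base = rng.normal(np.log(200.0), 0.7, size=design.n_genes)
    out = {}
    for ph in PHENOTYPES:
        n = ds.n_samples[ph]
        log_mu = np.tile(log_base[:, None], (1, n))
        for mod in design.modules:
            z = rng.normal(size=n)
            if not mod.active_in(ph):
                continue
            rho = mod.within_correlation
            idx = np.array(mod.member_genes)
            # delta-method log-count variance at the baseline mean
            v = alpha + np.exp(-log_base[idx])
            beta = np.sqrt(v * rho / (1.0 - rho))
            log_mu[idx] = log_base[idx, None] + beta[:, None] * z[None, :]
        mu = np.exp(log_mu)
        counts = rng.negative_binomial(n=1.0 / alpha, p=1.0 / (1.0 + alpha * mu))
        cols = [f"{ds.dataset_id}_{ph}_s{i}" for i in range(n)]
        out[ph] = pd.DataFrame(counts, index=design.gene_ids, columns=cols)
    return out


def generate(design: SyntheticDesign) -> tuple[list[ExpressionMatrix], list[ModuleSpec]]:
    """Generate one :class:`ExpressionMatrix` per dataset per phenotype.

    Returns the matrices (ordered dataset-major, LA before HA) together with
    the ground-truth module list. Fully reproducible from ``design.seed``.
    """
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(len(design.datasets))
    matrices: list[ExpressionMatrix] = []
    for ds, child in zip(design.datasets, children):
        rng = np.random.default_rng(child)
        maker = _count_dataset if ds.platform == "count" else _intensity_dataset
        frames = maker(design, ds, rng)
        for ph in PHENOTYPES:
            matrices.append(
                ExpressionMatrix(
                    dataset_id=ds.dataset_id,
                    platform=ds.platform,
                    phenotype=ph,
                    values=frames[ph],
                )
            )
    return matrices, list(design.modules)


def example_design(
    seed: int = 0,
    n_genes: int = 300,
    module_size: int = 30,
    within_correlation: float = 0.85,
    la_only_module: bool = False,
    n_samples: int = 20,
) -> SyntheticDesign:
    """The package's reference design: three populations, two phenotype groups.

    Three planted modules of ``module_size`` genes at the given within-module
    correlation; one count platform and two intensity platforms, mirroring an
    RNA-seq population alongside two microarray populations. When
    ``la_only_module`` is set, the third module is planted only in the LA
    group, emulating a phenotype-specific signature cluster.
    """
    sizes = {"LA": n_samples, "HA": n_samples}
    datasets = (
        DatasetSpec("DuF2", "count", sizes),
        DatasetSpec("Duroc", "intensity", sizes),
        DatasetSpec("Landrace", "intensity", sizes),
    )
    modules = tuple(
        ModuleSpec(
            module_id=f"M{k}",
            member_genes=tuple(range(k * module_size, (k + 1) * module_size)),
            within_correlation=within_correlation,
            present_in_phenotype="LA" if (la_only_module and k == 2) else "both",
        )
        for k in range(3)
    )
    return SyntheticDesign(
        n_genes=n_genes, datasets=datasets, modules=modules, seed=seed
    )


# ---------------------------------------------------------------------------
# Ontology / annotation fixture
# ---------------------------------------------------------------------------

def generate_ontology_fixture(
    n_terms: int,
    max_depth: int,
    genes: Sequence[str],
    seed: int,
    planted_genes: Sequence[str] | None = None,
) -> tuple[OntologyGraph, AnnotationTable]:
    """A random rooted GO-like DAG plus true-path-propagated annotations.

    One designated term annotates exactly ``planted_genes`` (default: the
    first ``min(10, len(genes))`` genes) so enrichment tests have a planted
    positive; the remaining genes are annotated to random non-root terms.
    Annotations are up-propagated to all ancestors (true-path rule).
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root = terms[0]
    g = nx.DiGraph()
    g.add_node(root)
    depth = {root: 0}
    for t in terms[1:]:
        candidates = [u for u in g.nodes if depth[u] < max_depth]
        if not candidates:
            candidates = [root]
        n_parents = 1 + int(rng.random() < 0.3 and len(candidates) > 1)
        parents = rng.choice(len(candidates), size=n_parents, replace=False)
        g.add_node(t)
        for j, pi in enumerate(parents):
            rel = "is_a" if (j == 0 or rng.random() < 0.7) else "part_of"
            g.add_edge(t, candidates[pi], relation=rel)
        depth[t] = 1 + max(depth[candidates[pi]] for pi in parents)
    namespaces = {t: "biological_process" for t in terms}
    names = {t: f"synthetic process {i}" for i, t in enumerate(terms)}
    onto = OntologyGraph(graph=g, names=names, namespaces=namespaces)

    genes = list(genes)
    if planted_genes is None:
        planted_genes = genes[: min(10, len(genes))]
    planted_set = set(planted_genes)
    # deepest term not annotating anything yet becomes the planted term
    planted_term = max(terms[1:], key=lambda t: (depth[t], t))
    gene_to_terms: dict[str, set[str]] = {}
    for gname in planted_genes:
        gene_to_terms.setdefault(gname, set()).add(planted_term)
    other_terms = [t for t in terms[1:] if t != planted_term]
    for gname in genes:
        if gname in planted_set:
            continue
        k = 1 + int(rng.integers(0, 3))
        chosen = rng.choice(len(other_terms), size=min(k, len(other_terms)), replace=False)
        gene_to_terms.setdefault(gname, set()).update(other_terms[i] for i in chosen)
    ann = propagate_annotations(
        AnnotationTable({g_: frozenset(t) for g_, t in gene_to_terms.items()},
                        "biological_process"),
        onto,
    )
    return onto, ann


def propagate_annotations(ann: AnnotationTable, onto: OntologyGraph) -> AnnotationTable:
    """Up-propagate annotations to every ancestor term (true-path rule)."""
    out: dict[str, frozenset[str]] = {}
    closure_cache: dict[str, set[str]] = {}
    for gname, terms in ann.gene_to_terms.items():
        full: set[str] = set()
        for t in terms:
            rt = onto.resolve(t)
            if rt not in closure_cache:
                closure_cache[rt] = onto.ancestors(rt, include_self=True)
            full |= closure_cache[rt]
        out[gname] = frozenset(full)
    return AnnotationTable(out, ann.namespace)


def write_design_outputs(
    design: SyntheticDesign, out_dir: str | Path
) -> list[Path]:
    """Materialise a design as TSV matrices plus a ground-truth JSON file."""
    from .io_formats import write_expression

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrices, modules = generate(design)
    paths = []
    for m in matrices:
        p = out_dir / f"{m.dataset_id}_{m.phenotype}.tsv"
        write_expression(m, p)
        paths.append(p)
    truth = {
        "seed": design.seed,
        "n_genes": design.n_genes,
        "modules": [
            {
                "module_id": m.module_id,
                "genes": [gene_id(i) for i in m.member_genes],
                "within_correlation": m.within_correlation,
                "present_in_phenotype": m.present_in_phenotype,
            }
            for m in modules
        ],
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths.append(truth_path)
    return paths
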