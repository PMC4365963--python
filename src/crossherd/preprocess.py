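"""Raw matrices -> analysis-ready, gene-intersected, phenotype-grouped sets.

Count matrices are placed on the intensity scale with a log2 counts-per-million
transform (prior count 0.5); probe-level microarray matrices are collapsed to
one row per gene by keeping the probe with the largest between-sample
variance; all matrices are then restricted to their common gene set and
regrouped by phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PHENOTYPES, ExpressionMatrix, ProbeMap

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSet",
    "log_cpm",
    "collapse_probes",
    "intersect_genes",
    "group_by_phenotype",
]


@dataclass
class PhenotypeSet:
    """All expression matrices of one phenotype over an identical gene universe."""

    phenotype: str
    matrices: list[ExpressionMatrix]

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if not self.matrices:
            raise ValueError("empty phenotype set")
        genes = self.matrices[0].gene_ids
        for m in self.matrices[1:]:
            if m.gene_ids != genes:
                raise ValueError(
                    f"dataset {m.dataset_id}: gene universe differs from "
                    f"{self.matrices[0].dataset_id}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.matrices[0].gene_ids

    @property
    def dataset_ids(self) -> list[str]:
        return [m.dataset_id for m in self.matrices]


def log_cpm(counts: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count, per sample.

    ``value[g,s] = log2(1e6 * (count[g,s] + prior) / (libsize[s] + 2*prior))``.
    The prior keeps all-zero genes finite. The returned matrix is labelled
    ``intensity`` so downstream stages treat it like microarray data.
    """
    if counts.platform != "count":
        raise ValueError("log_cpm expects a count-valued matrix")
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"zero library size in sample {bad!r}")
    transformed = np.log2(1e6 * (arr + prior_count) / (lib + 2.0 * prior_count))
    values = pd.DataFrame(
        transformed, index=counts.values.index, columns=counts.values.columns
    )
    return counts.with_values(values, platform="intensity")


def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """One row per gene: keep the mapped probe with the largest sample variance.

    Variance uses the unbiased (n-1) denominator; ties keep the
    lexicographically smallest probe id. Probes absent from the map are
    dropped with a logged count.
    """
    probes = [p for p in m.values.index if p in pm.probe_to_gene]
    n_unmapped = m.n_genes - len(probes)
    if n_unmapped:
        logger.info(
            "collapse_probes(%s): dropped %d unmapped probes", m.dataset_id, n_unmapped
        )
    if not probes:
        raise ValueError(f"dataset {m.dataset_id}: no probes overlap the probe map")
    sub = m.values.loc[probes]
    variances = sub.var(axis=1, ddof=1)
    frame = pd.DataFrame(
        {
            "probe": probes,
            "gene": [pm.probe_to_gene[p] for p in probes],
            "variance": variances.to_numpy(),
        }
    )
    # max variance wins; ties resolved by smallest probe id
    frame = frame.sort_values(["gene", "variance", "probe"], ascending=[True, False, True])
    best = frame.drop_duplicates("gene", keep="first")
    values = sub.loc[best["probe"]].copy()
    values.index = best["gene"].to_numpy()
    values = values.sort_index()
    return m.with_values(values)


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the sorted common gene set (identical order)."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes common to all matrices")
    order = sorted(common)
    return [m.with_values(m.values.loc[order]) for m in matrices]


def group_by_phenotype(
    matrices: list[ExpressionMatrix], allow_single: bool = False
) -> tuple[PhenotypeSet, PhenotypeSet]:
    """Split matrices into an LA set and an HA set over the common universe.

    The joint-CDF meta-analysis needs at least two datasets per phenotype to
    be meaningful; a singleton set raises unless ``allow_single`` is set.
    """
    groups: dict[str, list[ExpressionMatrix]] = {ph: [] for ph in PHENOTYPES}
    for m in matrices:
        groups[m.phenotype].append(m)
    for ph, ms in groups.items():
        if len(ms) < 2 and not allow_single:
            raise ValueError(
                f"phenotype {ph}: {len(ms)} dataset(s); need >=2 "
                "(pass allow_single=True to override)"
            )
        if not ms:
            raise ValueError(f"phenotype {ph}: no datasets")
    return PhenotypeSet("LA", groups["LA"]), PhenotypeSet("HA", groups["HA"])
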