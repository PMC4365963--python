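"""Cross-dataset co-expression networks from rank-ratio joint probabilities.

For each dataset of a phenotype group, Pearson correlations are computed for
all unordered gene pairs and converted to *rank ratios*: the rank of a pair
among all pairs ordered by absolute correlation, divided by the number of
pairs (rank 1 = smallest |r|; ties get the average rank). A pair observed in
``n`` datasets thus yields ``n`` rank ratios in (0, 1]. Under the null that
the pair is unremarkable in every dataset, these behave like ``n``
independent uniforms, and the joint cumulative probability that the sorted
ratios dominate the uniform order statistics,

    P(r_1, ..., r_n) = n! * int_0^{r_(1)} int_{s_1}^{r_(2)} ...
                       int_{s_{n-1}}^{r_(n)} ds_n ... ds_1,

is used as the meta-analytic edge weight: it equals the probability that the
i-th smallest of n independent uniforms is <= r_(i) for every i, so weights
near 1 mean the pair ranks high in every dataset. Pairs whose signed
correlation is not strictly above the pruning threshold (+0.50 by default) in
*every* dataset are discarded before network construction, which removes both
weakly correlated pairs and pairs with conflicting directionality.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix
from .preprocess import PhenotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "pair_count",
    "pearson_pairs",
    "rank_ratios",
    "joint_cdf",
    "joint_cdf_many",
    "build_pair_table",
    "prune_pairs",
    "build_network",
    "phenotype_network",
]

MAX_JOINT_DIMENSIONS = 10


def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs, n*(n-1)/2."""
    return n_genes * (n_genes - 1) // 2


def pearson_pairs(m: ExpressionMatrix, block_size: int = 1024) -> pd.DataFrame:
    """Pearson correlation for every unordered gene pair of one matrix.

    Genes with zero variance across samples are dropped with a logged
    warning. Pairs are emitted in canonical order: genes sorted by id, pair
    (i, j) with i < j in row-major order. Correlations are computed in
    row blocks of ``block_size`` genes against the full standardized matrix;
    results are independent of the block size.
    """
    if m.n_samples < 3:
        raise ValueError(f"dataset {m.dataset_id}: need >=3 samples for correlation")
    values = m.values.sort_index()
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "pearson_pairs(%s): dropped %d zero-variance genes", m.dataset_id, n_dropped
        )
    arr = arr[keep]
    genes = values.index[keep].to_numpy()
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"dataset {m.dataset_id}: fewer than 2 genes with variance")
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    z = centered / norms[:, None]
    chunks = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = z[start:stop] @ z.T  # (stop-start) x n correlations
        for local, i in enumerate(range(start, stop)):
            row = block[local, i + 1 :]
            chunks.append(row)
    r = np.clip(np.concatenate(chunks) if chunks else np.empty(0), -1.0, 1.0)
    ii, jj = np.triu_indices(n, k=1)
    return pd.DataFrame({"gene_a": genes[ii], "gene_b": genes[jj], "r": r})


def rank_ratios(correlations: np.ndarray) -> np.ndarray:
    """Rank ratios of |r|: ascending average ranks divided by the pair count."""
    r = np.asarray(correlations, dtype=float)
    if r.size == 0:
        raise ValueError("empty correlation list")
    return rankdata(np.abs(r), method="average") / r.size


def joint_cdf(ratios) -> float:
    """Exact joint CDF of uniform order statistics at the sorted rank ratios.

    Evaluates the iterated integral by polynomial integration from the
    innermost variable outward, carrying exact coefficients in the next
    integration variable; the result is the probability that the i-th
    smallest of n independent uniforms is <= r_(i) for all i.
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    n = r.size
    if n == 0 or n > MAX_JOINT_DIMENSIONS:
        raise ValueError(f"need 1..{MAX_JOINT_DIMENSIONS} ratios, got {n}")
    if (r < 0).any() or (r > 1).any():
        raise ValueError("rank ratios must lie in [0, 1]")
    # poly holds coefficients (ascending powers) of the integrand in the
    # current integration variable; innermost integral of 1 over
    # [s_{n-1}, r_n] gives r_n - s_{n-1}.
    poly = np.array([1.0])
    for upper in r[::-1]:
        anti = np.concatenate(([0.0], poly / np.arange(1, poly.size + 1)))
        at_upper = float(np.polyval(anti[::-1], upper))
        poly = -anti
        poly[0] += at_upper
    # outermost lower limit is 0: after the loop poly holds the constant value
    return float(math.factorial(n) * poly[0])


def joint_cdf_many(ratio_matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`joint_cdf` for a (pairs x datasets) ratio matrix."""
    mat = np.asarray(ratio_matrix, dtype=float)
    return np.array([joint_cdf(row) for row in mat])


def build_pair_table(pset: PhenotypeSet, block_size: int = 1024) -> pd.DataFrame:
    """Per-pair correlations and rank ratios for every dataset of a phenotype.

    Columns: ``gene_a``, ``gene_b``, then ``r_<dataset>`` and
    ``ratio_<dataset>`` per dataset. Rank ratios are computed within each
    dataset over *all* of its pairs before any pruning. Pairs are restricted
    to genes with non-zero variance in every dataset.
    """
    table: pd.DataFrame | None = None
    for m in pset.matrices:
        pairs = pearson_pairs(m, block_size=block_size)
        pairs[f"ratio_{m.dataset_id}"] = rank_ratios(pairs["r"].to_numpy())
        pairs = pairs.rename(columns={"r": f"r_{m.dataset_id}"})
        table = pairs if table is None else table.merge(
            pairs, on=["gene_a", "gene_b"], how="inner"
        )
    assert table is not None
    return table


def prune_pairs(
    pair_table: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Keep pairs whose signed correlation exceeds ``threshold`` in every dataset."""
    r_cols = [c for c in pair_table.columns if c.startswith("r_")]
    if not r_cols:
        raise ValueError("pair table has no correlation columns")
    mask = (pair_table[r_cols] > threshold).all(axis=1)
    return pair_table.loc[mask].reset_index(drop=True)


def build_network(retained: pd.DataFrame, phenotype: str) -> nx.Graph:
    """Weighted co-expression graph from retained pairs.

    Each edge carries its per-dataset correlations (``cor_<dataset>``), the
    joint cumulative probability (``joint_cdf``) and a ``weight`` alias of
    the latter for clustering. An empty pair list yields an empty network.
    """
    net = nx.Graph(phenotype=phenotype)
    if retained.empty:
        logger.info("build_network(%s): no retained pairs, empty network", phenotype)
        return net
    r_cols = [c for c in retained.columns if c.startswith("r_")]
    ratio_cols = [c for c in retained.columns if c.startswith("ratio_")]
    if "joint_cdf" in retained.columns:
        weights = retained["joint_cdf"].to_numpy()
    else:
        weights = joint_cdf_many(retained[ratio_cols].to_numpy())
    for row, w in zip(retained.itertuples(index=False), weights):
        attrs = {f"cor_{c[2:]}": float(getattr(row, c)) for c in r_cols}
        attrs["joint_cdf"] = float(w)
        attrs["weight"] = float(w)
        net.add_edge(row.gene_a, row.gene_b, **attrs)
    return net


def phenotype_network(
    pset: PhenotypeSet, threshold: float = 0.5, block_size: int = 1024
) -> tuple[nx.Graph, dict[str, int]]:
    """Full co-expression network construction for one phenotype group.

    Returns the network and a stage-count manifest (pairs computed, pairs
    retained, nodes, edges).
    """
    table = build_pair_table(pset, block_size=block_size)
    retained = prune_pairs(table, threshold=threshold)
    net = build_network(retained, pset.phenotype)
    counts = {
        "pairs_computed": int(len(table)),
        "pairs_retained": int(len(retained)),
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
    }
    logger.info("phenotype_network(%s): %s", pset.phenotype, counts)
    return net, counts
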