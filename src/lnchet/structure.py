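"""Descriptive heterogeneity analyses.

Per-cell detection rates, all-pairs Pearson correlations split within/between
tumor of origin, PCA on top-variance genes, the union-of-top-abundant gene
panel from population controls, and hierarchical clustering with Newick
export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.decomposition import PCA

from .matrix import LOG2_TPM1, ExpressionMatrix, group_of

logger = logging.getLogger(__name__)


def percent_expressed(m: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Per cell, the fraction of the given genes detected (value > 0)."""
    sub = m.subset(features=genes)
    return (sub.values > 0).sum(axis=0) / len(genes)


@dataclass
class CorrelationSummary:
    pairs: pd.DataFrame  # sample_a, sample_b, within_group, r
    group_summary: pd.DataFrame  # per scope: min, q1, median, q3, max


def pairwise_correlations(m: ExpressionMatrix, meta: pd.DataFrame) -> CorrelationSummary:
    """Pearson r over the gene vector for every unordered cell pair."""
    if m.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    arr = m.values.to_numpy()
    sd = arr.std(axis=0)
    if (sd == 0).any():
        logger.warning(
            "%d constant cell vectors; their correlations are NaN", int((sd == 0).sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr.T)
    groups = group_of(meta).reindex(m.sample_ids)
    ids = m.sample_ids
    iu = np.triu_indices(len(ids), k=1)
    pairs = pd.DataFrame(
        {
            "sample_a": np.asarray(ids)[iu[0]],
            "sample_b": np.asarray(ids)[iu[1]],
            "within_group": (
                groups.to_numpy()[iu[0]] == groups.to_numpy()[iu[1]]
            ),
            "r": corr[iu],
        }
    )
    rows = []
    for scope, sub in pairs.groupby(pairs["within_group"].map({True: "within", False: "between"})):
        r = sub["r"].dropna()
        if len(r):
            rows.append(
                (scope, r.min(), r.quantile(0.25), r.median(), r.quantile(0.75), r.max())
            )
    summary = pd.DataFrame(rows, columns=["scope", "min", "q1", "median", "q3", "max"])
    return CorrelationSummary(pairs, summary)


def top_variance_genes(m: ExpressionMatrix, n: int = 500) -> list[str]:
    """The n genes with largest variance across samples; ties keep input order."""
    if n > m.shape[0]:
        raise ValueError(f"requested {n} genes but matrix has {m.shape[0]}")
    var = m.values.var(axis=1, ddof=1)
    # stable sort on -variance preserves input order among ties
    order = np.argsort(-var.to_numpy(), kind="stable")[:n]
    return list(m.values.index[np.sort(order)])


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    genes: list[str]


def run_pca(m: ExpressionMatrix, genes: list[str], n_components: int = 3) -> PCAResult:
    """Centered PCA of samples in the space of the given genes."""
    if m.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    sub = m.subset(features=genes)
    max_comp = min(sub.shape[1] - 1, len(genes))
    if n_components > max_comp:
        logger.warning("reducing n_components from %d to %d", n_components, max_comp)
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(sub.values.to_numpy().T)
    return PCAResult(
        pd.DataFrame(
            coords,
            index=sub.sample_ids,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        pca.explained_variance_ratio_,
        list(genes),
    )


def top_abundant_union(pop: ExpressionMatrix, k: int = 50) -> list[str]:
    """Union over population controls of each control's k most abundant genes.

    Abundance is the log2(TPM+1) value in that control.  The union is
    deduplicated with stable order (matrix feature order).
    """
    if pop.shape[1] < 1:
        raise ValueError("need at least one population control")
    if k > pop.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {pop.shape[0]}")
    chosen: set[str] = set()
    for s in pop.sample_ids:
        col = pop.values[s].to_numpy()
        top = np.argsort(-col, kind="stable")[:k]
        chosen.update(pop.values.index[top])
    return [g for g in pop.feature_ids if g in chosen]


@dataclass
class ClusteringResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    linkage: str
    distance: str


def _distance(arr: np.ndarray, metric: str) -> np.ndarray:
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN; cannot cluster")
    if metric == "correlation":
        return ssd.pdist(arr, metric="correlation")
    if metric == "euclidean":
        return ssd.pdist(arr, metric="euclidean")
    raise ValueError(f"unknown distance {metric!r}")


def hier_cluster(
    m: ExpressionMatrix, linkage: str = "average", distance: str = "correlation"
) -> ClusteringResult:
    """Agglomerative clustering of rows and columns; deterministic leaf orders."""
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    arr = m.values.to_numpy()
    row_link = sch.linkage(_distance(arr, distance), method=linkage)
    col_link = sch.linkage(_distance(arr.T, distance), method=linkage)
    row_order = [m.feature_ids[i] for i in sch.leaves_list(row_link)]
    col_order = [m.sample_ids[i] for i in sch.leaves_list(col_link)]
    return ClusteringResult(row_order, col_order, row_link, col_link, linkage, distance)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
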