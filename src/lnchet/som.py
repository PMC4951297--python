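"""Toroidal hexagonal self-organizing maps for gene expression portraits.

Genes (as z-score vectors across cells) are the training data; each lattice
unit carries a codebook vector in cell space.  The map is sized by the
heuristic M = 5 * sqrt(N) units for N training genes, initialized along the
top principal components, and trained online with a bubble neighborhood, the
learning rate declining linearly from 0.05 to 0.01 and the radius from d
(the 2/3 quantile of all unit-to-unit lattice distances) to 2 over all
updates.  After training, every gene is mapped to its best-matching unit
(BMU); the u-matrix (mean codebook distance of each unit to its six hex
neighbors) seeds clusters at its local minima, and remaining units join the
seed with the nearest codebook.  A cell's "component portrait" assigns to
each unit the mean z-score, in that cell, of the genes it houses.

Lattice geometry: axial hex coordinates with odd-row offset.  Unit i sits at
row = i // xdim, col = i % xdim, planar position
(col + 0.5*(row % 2), row * sqrt(3)/2).  Toroidal distances take the minimum
planar distance over the 9 torus images; neighbor sets use offset arithmetic
with modular wrap (always 6 neighbors).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_ROW_H = math.sqrt(3.0) / 2.0

# neighbor offsets (drow, dcol) for even and odd rows, odd-row-offset layout
_NEIGHBOR_OFFSETS = {
    0: ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)),
    1: ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)),
}


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def grid_size(n_genes: int) -> tuple[int, int]:
    """Lattice dimensions from the 5*sqrt(N)-units heuristic."""
    if n_genes < 4:
        raise ValueError("need at least 4 genes to size a map")
    m_units = _round_half_up(5.0 * math.sqrt(n_genes))
    xdim = _round_half_up(math.sqrt(m_units))
    ydim = _round_half_up(m_units / xdim)
    return xdim, ydim


@dataclass
class SOMGrid:
    """Toroidal hexagonal lattice with per-unit codebook vectors."""

    xdim: int
    ydim: int
    codebook: np.ndarray | None = None  # (n_units, dim)
    toroidal: bool = True
    _unit_dist: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_units(self) -> int:
        return self.xdim * self.ydim

    def positions(self) -> np.ndarray:
        """Planar (x, y) coordinates of all units, row-major."""
        idx = np.arange(self.n_units)
        row, col = idx // self.xdim, idx % self.xdim
        return np.column_stack([col + 0.5 * (row % 2), row * _ROW_H])

    def unit_distances(self) -> np.ndarray:
        """All-pairs toroidal lattice distances (minimum over 9 torus images)."""
        if self._unit_dist is None:
            pos = self.positions()
            dx = pos[:, 0][:, None] - pos[:, 0][None, :]
            dy = pos[:, 1][:, None] - pos[:, 1][None, :]
            best = np.full(dx.shape, np.inf)
            for sx in (-self.xdim, 0, self.xdim):
                for sy in (-self.ydim * _ROW_H, 0.0, self.ydim * _ROW_H):
                    best = np.minimum(best, (dx + sx) ** 2 + (dy + sy) ** 2)
            self._unit_dist = np.sqrt(best)
        return self._unit_dist

    def neighbors(self, unit: int) -> list[int]:
        """The 6 hex neighbors of a unit, wrapped around the torus."""
        row, col = unit // self.xdim, unit % self.xdim
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS[row % 2]:
            r, c = (row + dr) % self.ydim, (col + dc) % self.xdim
            out.append(r * self.xdim + c)
        return out


def init_codebooks(
    grid: SOMGrid,
    training: np.ndarray,
    n_pcs: int = 10,
    seed: int | np.random.Generator = 0,
    span_sd: float = 2.0,
) -> SOMGrid:
    """PCA initialization of the codebooks.

    The lattice's column axis spans +-``span_sd`` standard deviations along
    PC1, the row axis along PC2; coordinates on the remaining PCs (up to
    ``n_pcs``) are small seeded perturbations.  Every initial codebook lies
    in the affine span of the data mean and the top principal components.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_genes, dim = training.shape
    mean = training.mean(axis=0)
    codebook = np.tile(mean, (grid.n_units, 1))
    if n_pcs > 0:
        n_pcs = min(n_pcs, n_genes - 1, dim)
        if n_pcs < 1:
            logger.warning("degenerate data for PCA init; sampling training vectors")
            take = rng.integers(0, n_genes, grid.n_units)
            grid.codebook = training[take].copy()
            return grid
        pca = PCA(n_components=n_pcs, svd_solver="full")
        pca.fit(training)
        sds = np.sqrt(pca.explained_variance_)
        if not np.all(np.isfinite(sds)) or sds[0] == 0:
            logger.warning("degenerate covariance; sampling training vectors")
            take = rng.integers(0, n_genes, grid.n_units)
            grid.codebook = training[take].copy()
            return grid
        idx = np.arange(grid.n_units)
        row, col = idx // grid.xdim, idx % grid.xdim
        coord = np.zeros((grid.n_units, n_pcs))
        coord[:, 0] = np.linspace(-span_sd, span_sd, grid.xdim)[col] * sds[0]
        if n_pcs > 1:
            coord[:, 1] = np.linspace(-span_sd, span_sd, grid.ydim)[row] * sds[1]
        if n_pcs > 2:
            coord[:, 2:] = rng.normal(0.0, 0.1, (grid.n_units, n_pcs - 2)) * sds[2:][None, :]
        codebook = mean[None, :] + coord @ pca.components_
    grid.codebook = codebook
    return grid


def train(
    grid: SOMGrid,
    training: np.ndarray,
    epochs: int = 200,
    alpha: tuple[float, float] = (0.05, 0.01),
    radius: tuple[float | None, float] = (None, 2.0),
    neighborhood: str = "bubble",
    seed: int | np.random.Generator = 0,
    schedule: str = "per_presentation",
) -> tuple[SOMGrid, np.ndarray]:
    """Online SOM training.

    Each presentation finds the BMU (Euclidean; ties to the lowest unit
    index) and moves all units within the current lattice radius toward the
    vector by the current learning rate (bubble neighborhood; a Gaussian
    kernel is available).  Alpha and radius interpolate linearly over all
    ``epochs * n_vectors`` updates (or per epoch with
    ``schedule="per_epoch"``); the starting radius defaults to the 2/3
    quantile of all unit-to-unit lattice distances.  Presentation order is
    reshuffled each epoch from the seeded generator.

    Returns the trained grid and the per-epoch mean quantization error
    (mean distance of each presented vector to its BMU at presentation time).
    """
    if grid.codebook is None:
        raise ValueError("grid not initialized")
    if np.isnan(training).any():
        raise ValueError("NaN in training vectors")
    if len(training) < 1:
        raise ValueError("need at least one training vector")
    if neighborhood not in ("bubble", "gaussian"):
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    if schedule not in ("per_presentation", "per_epoch"):
        raise ValueError(f"unknown schedule {schedule!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codebook = grid.codebook.copy()
    dists = grid.unit_distances()
    r0 = radius[0] if radius[0] is not None else float(
        np.quantile(dists[np.triu_indices(grid.n_units, k=1)], 2.0 / 3.0)
    )
    r1, (a0, a1) = radius[1], alpha
    n = len(training)
    total = epochs * n
    qe = np.zeros(epochs)
    t = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        err = 0.0
        for i in order:
            frac = t / (total - 1) if total > 1 else 0.0
            if schedule == "per_epoch":
                frac = epoch / (epochs - 1) if epochs > 1 else 0.0
            a_t = a0 + (a1 - a0) * frac
            r_t = r0 + (r1 - r0) * frac
            x = training[i]
            diff = codebook - x[None, :]
            d2 = np.einsum("ij,ij->i", diff, diff)
            bmu = int(np.argmin(d2))
            err += math.sqrt(d2[bmu])
            if a_t != 0.0:
                if neighborhood == "bubble":
                    mask = dists[bmu] <= r_t
                    codebook[mask] -= a_t * diff[mask]
                else:
                    h = np.exp(-(dists[bmu] ** 2) / (2.0 * max(r_t, 1e-12) ** 2))
                    codebook -= (a_t * h)[:, None] * diff
            t += 1
        qe[epoch] = err / n
    grid.codebook = codebook
    return grid, qe


@dataclass
class SOMMapping:
    bmu: pd.Series  # gene -> unit index
    quantization_error: pd.Series  # gene -> Euclidean distance to BMU


def map_genes(grid: SOMGrid, vectors: pd.DataFrame) -> SOMMapping:
    """Best-matching unit per gene; ties broken toward the lowest unit index."""
    if grid.codebook is None:
        raise ValueError("grid not trained")
    X = vectors.to_numpy()
    if X.shape[1] != grid.codebook.shape[1]:
        raise ValueError(
            f"vector dim {X.shape[1]} != codebook dim {grid.codebook.shape[1]}"
        )
    # squared distances via the expansion; argmin takes the first (lowest) index
    c2 = np.einsum("ij,ij->i", grid.codebook, grid.codebook)
    d2 = c2[None, :] - 2.0 * X @ grid.codebook.T + np.einsum("ij,ij->i", X, X)[:, None]
    bmu = np.argmin(d2, axis=1)
    qerr = np.sqrt(np.maximum(np.take_along_axis(d2, bmu[:, None], axis=1)[:, 0], 0.0))
    return SOMMapping(
        pd.Series(bmu, index=vectors.index),
        pd.Series(qerr, index=vectors.index),
    )


def compute_umatrix(grid: SOMGrid) -> np.ndarray:
    """Per unit, the mean Euclidean codebook distance to its 6 hex neighbors."""
    if grid.codebook is None:
        raise ValueError("grid not trained")
    u = np.zeros(grid.n_units)
    for i in range(grid.n_units):
        nbrs = grid.neighbors(i)
        u[i] = np.mean(
            np.linalg.norm(grid.codebook[nbrs] - grid.codebook[i][None, :], axis=1)
        )
    return u


@dataclass
class ClusterAssignment:
    unit_cluster: np.ndarray  # unit -> cluster id (0-based)
    seeds: list[int]
    gene_cluster: pd.Series | None = None  # gene -> cluster id, via BMU


def cluster_units(grid: SOMGrid, u: np.ndarray) -> ClusterAssignment:
    """Seed clusters at u-matrix local minima and grow by codebook distance.

    A seed is a unit whose u-value is strictly below all six neighbors; a
    connected plateau of equal u-values that jointly beats every bordering
    neighbor contributes a single seed (its lowest unit index).  Every
    non-seed unit joins the seed with the smallest codebook Euclidean
    distance; ties go to the lowest seed index.  A constant u-matrix yields
    one cluster covering the map (with a warning).
    """
    n = grid.n_units
    neighbor_sets = [grid.neighbors(i) for i in range(n)]
    candidate = np.array(
        [u[i] <= min(u[j] for j in neighbor_sets[i]) for i in range(n)]
    )
    # group candidates into plateaus connected through equal-valued neighbors
    seeds: list[int] = []
    visited = np.zeros(n, dtype=bool)
    for i in range(n):
        if not candidate[i] or visited[i]:
            continue
        stack, comp = [i], []
        visited[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in neighbor_sets[k]:
                if candidate[j] and not visited[j] and u[j] == u[i]:
                    visited[j] = True
                    stack.append(j)
        border = {j for k in comp for j in neighbor_sets[k]} - set(comp)
        if all(u[j] > u[i] for j in border) or not border:
            seeds.append(min(comp))
    seeds.sort()
    if not seeds:
        warnings.warn("u-matrix has no local minimum; assigning a single cluster")
        return ClusterAssignment(np.zeros(n, dtype=int), [0])
    seed_cb = grid.codebook[seeds]
    diff = grid.codebook[:, None, :] - seed_cb[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    assign = np.argmin(d2, axis=1)  # ties -> lowest seed index
    return ClusterAssignment(assign, seeds)


def assign_genes(clusters: ClusterAssignment, mapping: SOMMapping) -> ClusterAssignment:
    """Attach gene -> cluster labels (via each gene's BMU) to an assignment."""
    clusters.gene_cluster = mapping.bmu.map(lambda b: int(clusters.unit_cluster[b]))
    return clusters


def cell_component(
    mapping: SOMMapping, z: pd.DataFrame, cell: str, n_units: int
) -> np.ndarray:
    """Portrait of one cell: per-unit mean z-score of the genes mapped there."""
    if cell not in z.columns:
        raise KeyError(f"unknown cell {cell!r}")
    vals = z[cell]
    out = np.full(n_units, np.nan)
    grouped = vals.groupby(mapping.bmu.reindex(z.index)).mean()
    out[grouped.index.astype(int)] = grouped.to_numpy()
    return out


def enrich_cluster(
    cluster_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Over-representation of a cluster's gene list in each gene set.

    One-sided hypergeometric tail P(X >= k) on the overlap, then
    Benjamini-Hochberg across sets.  Set members outside the universe are
    ignored.
    """
    if not universe or not gene_sets:
        raise ValueError("empty universe or gene-set collection")
    uni = set(universe)
    cl = set(cluster_genes)
    if not cl <= uni:
        raise ValueError("cluster genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        in_uni = uni & set(members)
        k = len(cl & in_uni)
        # P(X >= k), X ~ Hypergeom(N=|uni|, K=|set|, n=|cluster|)
        p = scipy.stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(cl))
        rows.append((name, len(in_uni), k, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def topology_preservation_test(
    grid: SOMGrid,
    mapping: SOMMapping,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Permutation test that planted gene sets map compactly on the lattice.

    The statistic is the mean (over the given sets) of the mean pairwise BMU
    lattice distance within each set; the null redraws size-matched random
    gene sets from all mapped genes.  Returns (observed, null mean,
    empirical p) with p = (1 + #{null <= obs}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dists = grid.unit_distances()
    bmu = mapping.bmu

    def set_stat(units: np.ndarray) -> float:
        iu = np.triu_indices(len(units), k=1)
        return float(dists[units[iu[0]], units[iu[1]]].mean())

    obs_sets = []
    for genes in gene_sets.values():
        present = [g for g in genes if g in bmu.index]
        if len(present) < 2:
            raise ValueError("gene set with fewer than 2 mapped genes")
        obs_sets.append(set_stat(bmu.loc[present].to_numpy()))
    observed = float(np.mean(obs_sets))
    sizes = [len([g for g in genes if g in bmu.index]) for genes in gene_sets.values()]
    all_units = bmu.to_numpy()
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = np.mean(
            [set_stat(all_units[rng.choice(len(all_units), size, replace=False)]) for size in sizes]
        )
    p = (1.0 + float((null <= observed).sum())) / (1.0 + n_perm)
    return observed, float(null.mean()), p
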