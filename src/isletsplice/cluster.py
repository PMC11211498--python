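"""PCA embedding of splicing profiles and shared-nearest-neighbor clustering.

Cells are embedded by principal components of the (imputed) psi matrix, then
clustered on a shared-nearest-neighbor (SNN) graph: a k-nearest-neighbor
graph in PC space whose edges are reweighted by the Jaccard overlap of the
two endpoints' neighbor sets, pruned below a cutoff, and partitioned by
Leiden modularity optimization at a given resolution.  Defaults (top 10 PCs,
resolution 1.2, k = 20, prune = 1/15) follow common single-cell practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ValidationError

__all__ = ["EmbeddingResult", "ClusterAssignment", "pca_embed", "snn_cluster"]


@dataclass
class EmbeddingResult:
    """Per-cell PC scores plus loadings and explained variance."""

    scores: np.ndarray                # cells x n_pcs
    loadings: np.ndarray              # n_pcs x events
    explained_variance_ratio: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


@dataclass
class ClusterAssignment:
    """Integer cluster labels (contiguous from 1) with the parameters used."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)


def pca_embed(matrix: np.ndarray, n_pcs: int = 10,
              scale: bool = False) -> EmbeddingResult:
    """Top principal components of cells from a complete psi matrix.

    Events (columns) are centered; unit scaling is off by default since psi
    is already bounded.  ``n_pcs`` is reduced with a warning when it reaches
    the rank of the centered matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("embedding input must be complete and finite")
    centered = X - X.mean(axis=0)
    if scale:
        sd = centered.std(axis=0)
        centered = centered / np.where(sd > 0, sd, 1.0)
    total_var = centered.var(axis=0).sum()
    if total_var <= 1e-12:
        warnings.warn("input matrix is constant; returning empty embedding")
        return EmbeddingResult(np.zeros((X.shape[0], 0)),
                               np.zeros((0, X.shape[1])), np.zeros(0))
    rank = np.linalg.matrix_rank(centered)
    if n_pcs >= rank:
        warnings.warn(f"n_pcs={n_pcs} >= rank {rank}; reducing")
        n_pcs = max(rank - 1, 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(centered)
    return EmbeddingResult(scores, pca.components_,
                           pca.explained_variance_ratio_)


def snn_graph(scores: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> sparse.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph in PC space.

    Neighbor sets (of size k+1, including the cell itself) are intersected;
    edge weight = |A & B| / |A | B|; weights below ``prune`` are removed.
    """
    n = scores.shape[0]
    if n <= k_neighbors:
        warnings.warn(f"only {n} cells; reducing k_neighbors to {n - 1}")
        k_neighbors = n - 1
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    k1 = k_neighbors + 1
    rows = np.repeat(np.arange(n), k1)
    adj = sparse.csr_matrix((np.ones(rows.size), (rows, idx.ravel())),
                            shape=(n, n))
    inter = (adj @ adj.T).tocoo()             # |A & B| for all overlapping pairs
    union = 2 * k1 - inter.data
    jac = inter.data / union
    keep = jac >= prune
    g = sparse.coo_matrix((jac[keep], (inter.row[keep], inter.col[keep])),
                          shape=(n, n)).tocsr()
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def snn_cluster(scores, k_neighbors: int = 20, prune: float = 1 / 15,
                resolution: float = 1.2, seed: int = 0) -> ClusterAssignment:
    """Leiden community detection on the SNN graph of cells.

    ``scores`` may be an :class:`EmbeddingResult` or a cells x PCs array.
    Deterministic given ``seed``; labels are renumbered 1..K by decreasing
    cluster size.
    """
    if isinstance(scores, EmbeddingResult):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    g = snn_graph(scores, k_neighbors=k_neighbors, prune=prune)
    coo = sparse.triu(g, k=1).tocoo()
    graph = igraph.Graph(n=scores.shape[0],
                         edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                         edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    raw = np.asarray(part.membership)
    # relabel 1..K by decreasing size (ties broken by first occurrence)
    sizes = np.bincount(raw)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(1, order.size + 1)
    labels = remap[raw]
    return ClusterAssignment(labels, params={
        "k_neighbors": k_neighbors, "prune": prune,
        "resolution": resolution, "seed": seed})
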