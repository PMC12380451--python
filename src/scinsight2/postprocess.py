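"""Embedding normalization and joint Louvain clustering.

Fitted cell embeddings are refined before clustering: each metagene column is
scaled to unit SD (so no single factor dominates the metric) and each cell
row is scaled to unit Euclidean norm (so clustering compares metagene score
*profiles*, not magnitudes).  Cells are then clustered by Louvain modularity
optimization on a shared-nearest-neighbor graph with Jaccard edge weights.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

import igraph

logger = logging.getLogger("scinsight2")


@dataclass
class ClusterResult:
    labels: np.ndarray
    normalized_U: np.ndarray
    graph_k: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def normalize_embeddings(U: np.ndarray, mode: str = "column_scale_row_l2") -> np.ndarray:
    """Scale factor columns to unit SD, then cell rows to unit L2 norm.

    ``mode`` may be ``none``, ``column_scale`` or ``column_scale_row_l2``
    (default).  Zero-SD columns and zero rows are left at zero (the latter
    logged).  The result is invariant to positive rescaling of U.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if mode == "none":
        return U.copy()
    sd = U.std(axis=0)
    out = np.where(sd > 0, U / np.where(sd > 0, sd, 1.0), 0.0)
    if mode == "column_scale":
        return out
    norms = np.linalg.norm(out, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        logger.warning("%d cells have all-zero embeddings after scaling", int(zero_rows.sum()))
    out = out / np.where(zero_rows, 1.0, norms)[:, None]
    return out


def _snn_graph(U: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell keeps its k nearest neighbors (self included, Euclidean);
    an edge between neighboring cells i, j is weighted by the Jaccard overlap
    of their neighbor sets.
    """
    N = U.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(U)
    _, idx = nn.kneighbors(U)
    rows = np.repeat(np.arange(N), k)
    A = sp.csr_matrix((np.ones(N * k), (rows, idx.ravel())), shape=(N, N))
    shared = A @ A.T  # |N(i) ∩ N(j)|
    shared = sp.triu(shared.tocoo(), k=1).tocoo()
    jacc = shared.data / (2.0 * k - shared.data)
    keep = jacc > 0
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=N, edges=edges)
    g.es["weight"] = jacc[keep].tolist()
    return g


def cluster_cells(
    normalized_U: np.ndarray,
    k: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Louvain clustering of cells on an SNN graph of their embeddings."""
    U = np.atleast_2d(np.asarray(normalized_U, dtype=float))
    N = U.shape[0]
    if N <= k:
        raise ValueError(f"need more cells than neighbors (N={N}, k={k}); reduce k")
    g = _snn_graph(U, k)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    igraph.set_random_number_generator(random)  # restore the module default
    labels = np.asarray(part.membership, dtype=int)
    return ClusterResult(labels=labels, normalized_U=U, graph_k=k, resolution=resolution, seed=seed)
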