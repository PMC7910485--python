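"""KNN-graph construction, community detection and clustering-quality metrics.

Community detection is treated as a pluggable external algorithm; Leiden
(leidenalg) is the default because it is seedable, Louvain (igraph
multilevel) is available behind ``method="louvain"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import entropy as shannon_entropy
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics import pairwise_distances

_CHUNK = 1024  # rows per distance-matrix block


@dataclass
class KNNGraph:
    """Exact Euclidean k-nearest-neighbor graph (no self edges)."""

    adjacency: sp.csr_matrix  # symmetrized by union unless symmetrize=False
    k: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self):
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


@dataclass
class ClusterLabels:
    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def _knn_indices(U: np.ndarray, k: int, exclude_self: bool = True) -> np.ndarray:
    """Indices of the k nearest rows per row, ascending distance, ties broken
    toward the lower index (stable sort on the distance row)."""
    n = len(U)
    out = np.empty((n, k), dtype=np.int64)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        d = pairwise_distances(U[lo:hi], U)
        if exclude_self:
            d[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        order = np.argsort(d, axis=1, kind="stable")
        out[lo:hi] = order[:, :k]
    return out


def knn_graph(U: np.ndarray, k: int = 15, symmetrize: bool = True) -> KNNGraph:
    """Exact (brute-force) KNN graph in Euclidean space.

    Ties are broken toward the lower cell index; with ``symmetrize`` the
    directed adjacency is unioned with its transpose, so every node ends up
    with at least k incident edges.
    """
    U = np.asarray(U, dtype=float)
    n = len(U)
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nbrs = _knn_indices(U, k)
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix((np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n)).tocsr()
    if symmetrize:
        adj = adj.maximum(adj.T)
    return KNNGraph(adjacency=adj.tocsr(), k=k)


def cluster(
    graph: KNNGraph | sp.spmatrix,
    resolution: float = 1.0,
    seed: int = 1,
    method: str = "leiden",
) -> ClusterLabels:
    """Community detection on a (possibly weighted) adjacency.

    Deterministic given ``seed``; cluster ids are relabeled contiguously from
    0 in order of first appearance.
    """
    import igraph as ig

    adj = graph.adjacency if isinstance(graph, KNNGraph) else sp.csr_matrix(graph)
    if adj.shape[0] == 0 or adj.nnz == 0:
        raise ValueError("empty graph")
    coo = sp.triu(adj.maximum(adj.T), k=1).tocoo()
    g = ig.Graph(n=adj.shape[0],
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    weights = coo.data.tolist()
    if method == "leiden":
        import leidenalg as la

        part = la.find_partition(
            g, la.RBConfigurationVertexPartition, weights=weights,
            resolution_parameter=resolution, seed=seed, n_iterations=2)
        membership = np.asarray(part.membership)
    elif method == "louvain":
        import random as _random

        ig.set_random_number_generator(_random.Random(seed))
        part = g.community_multilevel(weights=weights, resolution=resolution)
        membership = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}")
    # contiguous ids from 0 in order of first appearance
    _, labels = np.unique(membership, return_inverse=True)
    first = {}
    relabel = np.empty(labels.max() + 1, dtype=np.int64)
    nxt = 0
    for lab in labels:
        if lab not in first:
            first[lab] = nxt
            nxt += 1
    for lab, new in first.items():
        relabel[lab] = new
    return ClusterLabels(labels=relabel[labels])


# ---------------------------------------------------------------------------
# metrics


def connectivity_index(U: np.ndarray, labels, K: int = 15) -> float:
    """Sum over cells of 1/i for each i-th nearest neighbor in a different cluster.

    Zero iff every cell's K nearest neighbors share its label; higher values
    mean clusters are less separated in the embedding.
    """
    lab = np.asarray(labels.labels if isinstance(labels, ClusterLabels) else labels)
    U = np.asarray(U, dtype=float)
    if K >= len(U):
        raise ValueError("K must be < n")
    nbrs = _knn_indices(U, K)
    differs = lab[nbrs] != lab[:, None]
    ranks = 1.0 / np.arange(1, K + 1)
    return float((differs * ranks).sum())


def coverage_entropy(
    embedding2d: np.ndarray,
    coverage: np.ndarray,
    top_fraction: float = 0.1,
    grid_bins: int = 50,
) -> float:
    """Shannon entropy (nats) of the highest-coverage cells over a 2-D grid.

    The ``top_fraction`` highest-coverage cells are histogrammed on a
    ``grid_bins`` x ``grid_bins`` partition of the bounding box of the whole
    embedding (so concentration of the deep cells in one region registers as
    low entropy); higher entropy means the deep cells are spread more
    uniformly across the embedding, i.e. less residual depth bias.
    """
    emb = np.asarray(embedding2d, dtype=float)
    if emb.ndim != 2 or emb.shape[1] != 2:
        raise ValueError("embedding2d must be n x 2")
    cov = np.asarray(coverage, dtype=float)
    n_top = max(1, int(round(top_fraction * len(cov))))
    top = np.argsort(-cov, kind="stable")[:n_top]
    if n_top < 10:
        warnings.warn(f"only {n_top} cells selected for coverage entropy")
    pts = emb[top]
    box = [(emb[:, 0].min(), emb[:, 0].max()), (emb[:, 1].min(), emb[:, 1].max())]
    H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=grid_bins, range=box)
    counts = H.ravel()
    return float(shannon_entropy(counts[counts > 0]))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant)."""
    a, b = _as_label_arrays(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = _as_label_arrays(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b))


def _as_label_arrays(a, b):
    a = np.asarray(a.labels if isinstance(a, ClusterLabels) else a)
    b = np.asarray(b.labels if isinstance(b, ClusterLabels) else b)
    if len(a) != len(b):
        raise ValueError(f"label length mismatch: {len(a)} vs {len(b)}")
    return a, b
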