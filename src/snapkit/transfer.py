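"""Projection of query cells onto a reference landmark embedding and
label transfer through scored mutual-nearest-neighbor anchors.

Query cells binned on the reference bin set are projected with the same
out-of-sample extension used for landmark embedding. In the joint space,
reference-query pairs that are mutually within each other's 5 nearest
neighbors become anchors; each anchor is scored by shared-neighbor
consistency, each query cell is given distance-decayed weights over its s
nearest anchors,

    D_ci = (1 - dist(c, a_i) / dist(c, a_s)) * S_ai,
    D~_ci = 1 - exp(-D_ci / (2/sd)^2),
    W_ci = D~_ci / sum_j D~_cj,

and label probabilities follow as P = W L with L the one-hot reference
labels. Query cells with no anchor, or whose best probability falls below a
confidence threshold, are flagged unassigned rather than forced into a class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_matrix import CellByBinMatrix
from .graph import _knn_indices
from .nystrom import NystromModel, extend
from sklearn.metrics import pairwise_distances


@dataclass
class ProjectionResult:
    U_query: np.ndarray

    def joint(self, U_ref: np.ndarray) -> np.ndarray:
        return np.vstack([U_ref, self.U_query])


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor (reference, query) pairs with consistency scores."""

    pairs: np.ndarray  # (n_anchors, 2): reference index, query index
    scores: np.ndarray = field(default=None)
    k_nearest: int = 5

    @property
    def n_anchors(self) -> int:
        return len(self.pairs)

    def anchored_queries(self) -> np.ndarray:
        return np.unique(self.pairs[:, 1]) if len(self.pairs) else np.array([], int)

    def unanchored_queries(self, n_query: int) -> np.ndarray:
        return np.setdiff1d(np.arange(n_query), self.anchored_queries())


@dataclass
class TransferWeights:
    W: np.ndarray  # query x anchors, rows sum to 1 (anchored queries)
    anchor_pairs: np.ndarray
    s: int


@dataclass
class LabelPrediction:
    P: np.ndarray  # query x clusters
    best_label: np.ndarray
    best_score: np.ndarray
    flagged: np.ndarray  # low confidence or no anchor
    classes: np.ndarray


def project_query(model: NystromModel, Y: CellByBinMatrix) -> ProjectionResult:
    """Project query cells onto the reference landmark eigenbasis."""
    if Y.n_cells and Y.X.shape[1] != model.landmark_X.shape[1]:
        raise ValueError(
            f"query has {Y.X.shape[1]} bins but the reference model expects "
            f"{model.landmark_X.shape[1]}; bin the query on the reference's kept_bins")
    return ProjectionResult(U_query=extend(model, Y))


def find_anchors(U_ref: np.ndarray, U_query: np.ndarray,
                 k_nearest: int = 5) -> AnchorSet:
    """Mutual k-nearest-neighbor pairs between reference and query embeddings."""
    U_ref = np.atleast_2d(U_ref)
    U_query = np.atleast_2d(U_query)
    if U_ref.shape[1] != U_query.shape[1]:
        raise ValueError("reference and query embeddings must share the rank")
    k = min(k_nearest, len(U_ref), len(U_query))
    d = pairwise_distances(U_ref, U_query)
    ref_nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    query_nbrs = np.argsort(d.T, axis=1, kind="stable")[:, :k]
    query_sets = [set(row) for row in query_nbrs]
    pairs = [(i, c) for i in range(len(U_ref)) for c in ref_nbrs[i]
             if i in query_sets[c]]
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return AnchorSet(pairs=pairs, k_nearest=k)


def score_anchors(anchors: AnchorSet, U_ref: np.ndarray, U_query: np.ndarray,
                  snn_k: int = 30,
                  rescale_quantiles: tuple[float, float] = (0.01, 0.90)) -> AnchorSet:
    """Score anchors by shared-nearest-neighbor consistency in the joint space.

    The raw score is the shared-neighbor count of the pair's two cells in the
    joint snn_k-NN graph divided by snn_k, rescaled between the stated
    quantiles of the raw scores and clipped to [0, 1].
    """
    if anchors.n_anchors == 0:
        raise ValueError("no anchors to score")
    joint = np.vstack([U_ref, U_query])
    n_ref = len(U_ref)
    k = min(snn_k, len(joint) - 1)
    nbrs = _knn_indices(joint, k)
    nbr_sets = [set(row) for row in nbrs]
    raw = np.array([
        len(nbr_sets[i] & nbr_sets[n_ref + c]) / k
        for i, c in anchors.pairs
    ])
    lo = np.quantile(raw, rescale_quantiles[0])
    hi = np.quantile(raw, rescale_quantiles[1])
    if hi > lo:
        scores = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    else:  # all anchors equally consistent
        scores = np.where(raw > 0, 1.0, 0.0)
    anchors.scores = scores
    return anchors


def transfer_weights(U_query: np.ndarray, anchors: AnchorSet,
                     s: int = 50, sd: float = 1.0) -> TransferWeights:
    """Distance-decayed weights from each query cell to its s nearest anchors.

    Distances are measured to the anchors' query-side cells. The s-th anchor
    receives weight 0 by construction; weights beyond it are 0; each row of W
    sums to 1. Queries whose decayed weights all vanish fall back to uniform
    weights over their s anchors, with a warning.
    """
    if anchors.n_anchors == 0:
        raise ValueError("need at least one anchor")
    if anchors.scores is None:
        raise ValueError("score the anchors first (score_anchors)")
    n_anchors = anchors.n_anchors
    s = min(s, n_anchors)
    anchor_pts = U_query[anchors.pairs[:, 1]]
    d = pairwise_distances(np.atleast_2d(U_query), anchor_pts)
    order = np.argsort(d, axis=1, kind="stable")[:, :s]
    rows = np.arange(len(U_query))[:, None]
    dist_s = d[rows, order[:, -1:]]
    ratio = np.divide(d[rows, order], dist_s,
                      out=np.zeros_like(d[rows, order]), where=dist_s > 0)
    D = (1.0 - ratio) * anchors.scores[order]
    Dt = 1.0 - np.exp(-D / (2.0 / sd) ** 2)
    W = np.zeros((len(U_query), n_anchors))
    np.put_along_axis(W, order, Dt, axis=1)
    rowsum = W.sum(axis=1)
    dead = rowsum == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} query cells had all-zero decayed "
                      "weights; using uniform weights over their anchors")
        for i in np.flatnonzero(dead):
            W[i, order[i]] = 1.0
        rowsum = W.sum(axis=1)
    W /= rowsum[:, None]
    return TransferWeights(W=W, anchor_pairs=anchors.pairs, s=s)


def predict_labels(weights: TransferWeights, ref_labels: np.ndarray,
                   threshold: float = 0.9,
                   no_anchor_queries: np.ndarray | None = None) -> LabelPrediction:
    """Label probabilities P = W L from anchor reference-side labels.

    ``ref_labels`` holds the hard cluster label of every reference cell; each
    anchor contributes its reference-side label. Queries whose best
    probability is below ``threshold`` (default per the high-confidence
    convention 0.9) or that are listed in ``no_anchor_queries`` are flagged.
    """
    ref_labels = np.asarray(ref_labels)
    classes, enc = np.unique(ref_labels, return_inverse=True)
    anchor_lab = enc[weights.anchor_pairs[:, 0]]
    L = np.zeros((len(anchor_lab), len(classes)))
    L[np.arange(len(anchor_lab)), anchor_lab] = 1.0
    P = weights.W @ L
    best_idx = np.argmax(P, axis=1)
    best_score = P[np.arange(len(P)), best_idx]
    flagged = best_score < threshold
    if no_anchor_queries is not None and len(no_anchor_queries):
        flagged[np.asarray(no_anchor_queries, dtype=int)] = True
    return LabelPrediction(P=P, best_label=classes[best_idx],
                           best_score=best_score, flagged=flagged,
                           classes=classes)


def transfer_coordinates(weights: TransferWeights,
                         ref_coords: np.ndarray) -> np.ndarray:
    """Infer query coordinates (e.g. t-SNE positions) as W times the anchors'
    reference-side coordinates — a convex combination per query."""
    ref_coords = np.asarray(ref_coords, dtype=float)
    anchor_coords = ref_coords[weights.anchor_pairs[:, 0]]
    return weights.W @ anchor_coords
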