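"""Landmark (Nystrom) low-rank embedding, out-of-sample extension and the
ensemble variant.

Computing and eigendecomposing the full n-by-n normalized Jaccard kernel is
quadratic in the number of cells. Instead, k landmark cells are drawn by
inverse-density sampling, the kernel restricted to landmarks is embedded as
usual, and every remaining cell v is projected onto the landmark eigenbasis:

    A_vk = D_vv^{-1/2} N_vk D_kk^{-1/2},   U_vk = A_vk U_kk / Lambda_kk,

where N_vk is the depth-normalized cross similarity to the landmarks and
D_vv row sums are taken over the landmarks. Stacking U_kk over U_vk gives the
joint embedding. Because a single landmark draw is stochastic, the ensemble
variant repeats the procedure p times with independent draws, builds a KNN
graph from each expert embedding and averages the binary adjacencies with
equal weights 1/p; community detection then runs on the weighted consensus
graph. The n-by-n similarity matrix is never materialized: peak similarity
storage is O(n * k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core_matrix import CellByBinMatrix
from .embedding import (
    DepthRegressionModel,
    PairwiseSimilarity,
    cross_jaccard,
    expected_jaccard,
    fit_depth_model,
    jaccard_matrix,
    normalize_jaccard,
    sample_by_density,
    spectral_embed,
)

#: eigenvalues at or below this are treated as numerically zero in Eq-style
#: divisions (rank guard)
EIGENVALUE_FLOOR = 1e-12


@dataclass
class NystromModel:
    """Everything needed to extend or project new cells onto the landmark basis."""

    landmark_indices: np.ndarray
    depth_model: DepthRegressionModel
    U_kk: np.ndarray
    eigenvalues: np.ndarray
    landmark_row_sums: np.ndarray
    landmark_p: np.ndarray
    rank: int
    landmark_X: sp.csr_matrix = field(repr=False, default=None)
    landmark_coverage: np.ndarray = field(repr=False, default=None)
    depth_corrected: bool = True

    @property
    def k(self) -> int:
        return len(self.landmark_indices)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("landmark_indices", data=self.landmark_indices)
            f.create_dataset("U_kk", data=self.U_kk)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("landmark_row_sums", data=self.landmark_row_sums)
            f.create_dataset("landmark_p", data=self.landmark_p)
            f.create_dataset("landmark_coverage", data=self.landmark_coverage)
            f.attrs["rank"] = self.rank
            f.attrs["depth_corrected"] = self.depth_corrected
            dm = self.depth_model
            f.attrs["beta"] = [dm.beta0, dm.beta1, dm.beta2]
            f.attrs["sample_size"] = dm.sample_size
            f.attrs["cap_value"] = dm.cap_value
            Xl = self.landmark_X.tocsr()
            g = f.create_group("landmark_X")
            g.create_dataset("data", data=Xl.data)
            g.create_dataset("indices", data=Xl.indices)
            g.create_dataset("indptr", data=Xl.indptr)
            g.attrs["shape"] = Xl.shape

    @classmethod
    def load(cls, path) -> "NystromModel":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["landmark_X"]
            Xl = sp.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]),
                shape=tuple(g.attrs["shape"]),
            )
            beta = f.attrs["beta"]
            dm = DepthRegressionModel(
                beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
                sample_size=int(f.attrs["sample_size"]),
                cap_value=float(f.attrs["cap_value"]),
            )
            return cls(
                landmark_indices=f["landmark_indices"][:],
                depth_model=dm,
                U_kk=f["U_kk"][:],
                eigenvalues=f["eigenvalues"][:],
                landmark_row_sums=f["landmark_row_sums"][:],
                landmark_p=f["landmark_p"][:],
                rank=int(f.attrs["rank"]),
                landmark_X=Xl,
                landmark_coverage=f["landmark_coverage"][:],
                depth_corrected=bool(f.attrs.get("depth_corrected", True)),
            )


@dataclass
class EnsembleGraph:
    """Equal-weight average of p symmetrized binary KNN adjacencies."""

    expert_graphs: list[sp.csr_matrix]
    weights: np.ndarray
    combined: sp.csr_matrix

    @property
    def p(self) -> int:
        return len(self.expert_graphs)


# ---------------------------------------------------------------------------
# kernel-level primitives (used directly by oracle tests and by transfer)


def landmark_embedding(N_kk: np.ndarray | PairwiseSimilarity, r: int):
    """Embed a landmark kernel; returns (U_kk, eigenvalues, landmark row sums)."""
    emb = spectral_embed(N_kk, r)
    return emb.U, emb.eigenvalues, emb.row_sums


def extend_embedding(
    N_vk: np.ndarray,
    U_kk: np.ndarray,
    eigenvalues: np.ndarray,
    landmark_row_sums: np.ndarray,
) -> np.ndarray:
    """Project rows with landmark similarities N_vk onto the landmark basis.

    Row sums of N_vk (degrees against the landmarks) must be positive; columns
    whose eigenvalue is at or below the numeric floor are zeroed rather than
    divided.
    """
    N_vk = np.atleast_2d(np.asarray(N_vk, dtype=float))
    d_v = N_vk.sum(axis=1)
    if (d_v <= 0).any():
        i = int(np.flatnonzero(d_v <= 0)[0])
        raise ValueError(f"cell {i} has zero similarity to every landmark")
    A_vk = N_vk / np.sqrt(d_v)[:, None] / np.sqrt(landmark_row_sums)[None, :]
    lam = np.asarray(eigenvalues, dtype=float)
    good = lam > EIGENVALUE_FLOOR
    U_vk = np.zeros((N_vk.shape[0], U_kk.shape[1]))
    U_vk[:, good] = (A_vk @ U_kk[:, good]) / lam[good]
    return U_vk


# ---------------------------------------------------------------------------
# data-level API


def _normalized_cross(model: NystromModel, X_rows: sp.csr_matrix,
                      coverage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Depth-normalized, capped similarity of arbitrary cells to the landmarks."""
    J = cross_jaccard(X_rows, model.landmark_X, coverage, model.landmark_coverage)
    E = expected_jaccard(p, model.landmark_p)
    pred = model.depth_model.predict(E)
    if (pred <= 0).any():
        i, j = np.unravel_index(int(np.argmin(pred)), pred.shape)
        raise ValueError(f"non-positive predicted similarity for cell {i} vs "
                         f"landmark {j}")
    N = J / pred
    return np.minimum(N, model.depth_model.cap_value)


def fit_landmarks(
    X: CellByBinMatrix,
    k: int = 10000,
    r: int = 20,
    seed: int = 1,
    sample_size: int = 2000,
    depth_correct: bool = True,
) -> NystromModel:
    """Draw landmarks by inverse-density sampling and embed their kernel."""
    n = X.n_cells
    if k > n:
        warnings.warn(f"k={k} landmarks exceeds n={n} cells; clamping to n")
        k = n
    if r >= k:
        raise ValueError(f"rank r={r} must be < k={k}")
    idx = np.sort(sample_by_density(X.coverage, k, seed=seed))
    Xl = X.X[idx].tocsr()
    cov = X.coverage[idx]
    p = X.p[idx]
    land = CellByBinMatrix(X=Xl, cell_barcodes=[X.cell_barcodes[i] for i in idx],
                           bin_coords=X.bin_coords, kept_bins=X.kept_bins)
    if depth_correct:
        dm = fit_depth_model(land, sample_size=sample_size, seed=seed)
        J = jaccard_matrix(land)
        E = expected_jaccard(p)
        N = normalize_jaccard(J, E, dm)
        dm.cap_value = N.cap  # cross pairs share the landmark-block cap
        N_kk = N.values
    else:
        dm = DepthRegressionModel(0.0, 1.0, 0.0, sample_size=k, cap_value=np.inf)
        N_kk = jaccard_matrix(land).values
    U_kk, lam, d_kk = landmark_embedding(N_kk, r)
    return NystromModel(
        landmark_indices=idx, depth_model=dm, U_kk=U_kk, eigenvalues=lam,
        landmark_row_sums=d_kk, landmark_p=p, rank=r,
        landmark_X=Xl, landmark_coverage=cov, depth_corrected=depth_correct,
    )


def extend(model: NystromModel, X_rest: CellByBinMatrix) -> np.ndarray:
    """Project non-landmark cells onto the landmark eigenbasis (rows U_vk)."""
    if X_rest.n_cells == 0:
        return np.zeros((0, model.rank))
    if X_rest.X.shape[1] != model.landmark_X.shape[1]:
        raise ValueError("query cells are not binned on the landmark bin set")
    if model.depth_corrected:
        N_vk = _normalized_cross(model, X_rest.X.tocsr(), X_rest.coverage, X_rest.p)
    else:
        N_vk = cross_jaccard(X_rest.X.tocsr(), model.landmark_X,
                             X_rest.coverage, model.landmark_coverage)
    return extend_embedding(N_vk, model.U_kk, model.eigenvalues,
                            model.landmark_row_sums)


def nystrom_embed(
    X: CellByBinMatrix,
    k: int,
    r: int,
    seed: int = 1,
    sample_size: int = 2000,
    depth_correct: bool = True,
) -> tuple[np.ndarray, NystromModel]:
    """Landmark embedding of a whole dataset, returned in the input cell order."""
    model = fit_landmarks(X, k=k, r=r, seed=seed, sample_size=sample_size,
                          depth_correct=depth_correct)
    n = X.n_cells
    rest = np.setdiff1d(np.arange(n), model.landmark_indices)
    U = np.zeros((n, r))
    U[model.landmark_indices] = model.U_kk
    if len(rest):
        X_rest = CellByBinMatrix(
            X=X.X[rest].tocsr(),
            cell_barcodes=[X.cell_barcodes[i] for i in rest],
            bin_coords=X.bin_coords, kept_bins=X.kept_bins)
        U[rest] = extend(model, X_rest)
    return U, model


def ensemble_embed(
    X: CellByBinMatrix,
    p_experts: int = 5,
    k: int = 10000,
    r: int = 20,
    knn_k: int = 15,
    seed: int = 1,
    sample_size: int = 2000,
) -> EnsembleGraph:
    """Average the KNN graphs of ``p_experts`` independent landmark embeddings.

    Expert j uses seed ``seed + j``; each expert's symmetrized binary KNN
    adjacency enters the consensus with weight 1/p, so combined edge weights
    are multiples of 1/p.
    """
    from .graph import knn_graph

    if p_experts < 1:
        raise ValueError("p_experts must be >= 1")
    graphs = []
    for j in range(p_experts):
        U, _ = nystrom_embed(X, k=k, r=r, seed=seed + j, sample_size=sample_size)
        g = knn_graph(U, k=knn_k).adjacency
        g.data = np.ones_like(g.data)  # binary symmetrized adjacency
        graphs.append(g.tocsr())
    weights = np.full(p_experts, 1.0 / p_experts)
    combined = sum(w * g for w, g in zip(weights, graphs)).tocsr()
    return EnsembleGraph(expert_graphs=graphs, weights=weights, combined=combined)
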