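"""Jaccard-kernel spectral embedding with sequencing-depth correction.

The observed Jaccard similarity J_ij between two binary accessibility profiles
is confounded by sequencing depth: for two biologically unrelated cells with
per-bin signal probabilities P_i and P_j, the expected ratio of intersection
over union is

    E_ij = P_i * P_j / (P_i + P_j - P_i * P_j),

which increases with either coverage. The confounder is removed ad hoc by
regressing J on a degree-2 polynomial in E (fitted on a depth-balanced sample
of cells) and dividing each observed value by its prediction,

    N_ij = J_ij / (b0 + b1 * E_ij + b2 * E_ij^2),

capping outliers at the 0.99 quantile. The normalized kernel is then
symmetric-normalized, A = D^{-1/2} N D^{-1/2} with D_ii = sum_j N_ij, and
eigendecomposed; the leading r eigenvectors are the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from .core_matrix import CellByBinMatrix

Kind = Literal["observed_jaccard", "expected", "normalized"]


@dataclass
class PairwiseSimilarity:
    """A symmetric cells-by-cells similarity matrix tagged with its kind."""

    values: np.ndarray
    kind: Kind
    cap: float | None = None  # set on normalized matrices

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DepthRegressionModel:
    """Quadratic fit of observed on expected Jaccard, J ~ b0 + b1 E + b2 E^2.

    ``cap_value`` is the 0.99 quantile of the normalized values among the
    sampled training pairs, reused to cap out-of-sample (cross) similarities.
    """

    beta0: float
    beta1: float
    beta2: float
    sample_size: int
    cap_value: float

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def predict(self, E: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * E + self.beta2 * E * E


@dataclass
class SpectralEmbedding:
    """Leading eigenvectors of A = D^{-1/2} N D^{-1/2}, eigenvalues descending."""

    U: np.ndarray
    eigenvalues: np.ndarray
    row_sums: np.ndarray
    r: int

    @property
    def n(self) -> int:
        return self.U.shape[0]


# ---------------------------------------------------------------------------
# kernels


def _dense_binary(X: sp.spmatrix) -> np.ndarray:
    return np.asarray(X.todense(), dtype=np.float32)


def jaccard_matrix(X: CellByBinMatrix | sp.spmatrix) -> PairwiseSimilarity:
    """Pairwise Jaccard similarity between binary rows: |x_i & x_j| / |x_i | x_j|."""
    if isinstance(X, CellByBinMatrix):
        cov = X.coverage
        barcodes = X.cell_barcodes
        X = X.X
    else:
        X = sp.csr_matrix(X)
        cov = np.asarray(X.sum(axis=1)).ravel()
        barcodes = None
    if (cov == 0).any():
        i = int(np.flatnonzero(cov == 0)[0])
        name = barcodes[i] if barcodes is not None else str(i)
        raise ValueError(f"cell {name!r} has zero coverage; remove it upstream")
    D = _dense_binary(X)
    inter = D @ D.T
    union = cov[:, None] + cov[None, :] - inter
    J = np.asarray(inter / union, dtype=np.float64)
    np.fill_diagonal(J, 1.0)
    return PairwiseSimilarity(J, "observed_jaccard")


def cross_jaccard(A: sp.spmatrix, B: sp.spmatrix,
                  cov_a: np.ndarray, cov_b: np.ndarray) -> np.ndarray:
    """Jaccard similarity between every row of A and every row of B."""
    inter = _dense_binary(A) @ _dense_binary(B).T
    union = cov_a[:, None] + cov_b[None, :] - inter
    return np.asarray(inter / union, dtype=np.float64)


def expected_jaccard(p_i: np.ndarray, p_j: np.ndarray | None = None) -> PairwiseSimilarity | np.ndarray:
    """Expected Jaccard of random binary vectors with signal probabilities P.

    With one argument, returns the symmetric PairwiseSimilarity among the
    cells of ``p_i``; with two, returns the cross matrix (rows: p_i) as a
    plain ndarray.
    """
    symmetric = p_j is None
    p_i = np.asarray(p_i, dtype=np.float64)
    p_j_arr = p_i if symmetric else np.asarray(p_j, dtype=np.float64)
    for p in (p_i, p_j_arr):
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("all P_i must lie in (0, 1]")
    prod = p_i[:, None] * p_j_arr[None, :]
    E = prod / (p_i[:, None] + p_j_arr[None, :] - prod)
    return PairwiseSimilarity(E, "expected") if symmetric else E


# ---------------------------------------------------------------------------
# depth-balanced sampling and regression


def sample_by_density(coverage: np.ndarray, size: int, seed: int = 1) -> np.ndarray:
    """Sample cell indices without replacement, inversely weighted by the
    kernel-density estimate of log10 coverage, so sparse regions of the depth
    distribution are retained."""
    coverage = np.asarray(coverage, dtype=np.float64)
    n = len(coverage)
    if size > n:
        raise ValueError(f"size {size} exceeds number of cells {n}")
    if (coverage <= 0).any():
        raise ValueError("all coverages must be positive")
    if size == n:
        return np.arange(n)
    logc = np.log10(coverage)
    try:
        dens = gaussian_kde(logc)(logc)  # Scott's rule bandwidth
        weights = 1.0 / np.maximum(dens, np.finfo(float).tiny)
    except np.linalg.LinAlgError:  # constant coverage -> uniform
        weights = np.ones(n)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=size, replace=False, p=weights, shuffle=False)


def _pair_values(J: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(J.shape[0], k=1)  # self-pairs excluded
    return J[iu], E[iu]


def fit_depth_model(
    X: CellByBinMatrix,
    sample_size: int = 2000,
    seed: int = 1,
    cap_quantile: float = 0.99,
) -> DepthRegressionModel:
    """Fit the quadratic depth regression on a density-balanced cell sample.

    min(sample_size, n) cells are drawn by :func:`sample_by_density`; observed
    and expected Jaccard are computed over all pairs among them (self-pairs
    excluded) and J is regressed on (1, E, E^2) by ordinary least squares.
    The cap is the ``cap_quantile`` quantile of the normalized sampled pairs.
    """
    n = X.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to fit the depth model")
    size = min(max(sample_size, 2), n)
    idx = sample_by_density(X.coverage, size, seed=seed)
    sub = X.X[idx].tocsr()
    cov = X.coverage[idx]
    p = X.p[idx]
    J = cross_jaccard(sub, sub, cov, cov)
    E = expected_jaccard(p).values
    j, e = _pair_values(J, E)
    beta, degenerate = _fit_quadratic(j, e)
    if degenerate:
        warnings.warn("expected Jaccard is constant across sampled pairs; "
                      "falling back to beta = (mean J, 0, 0)")
    pred = beta[0] + beta[1] * e + beta[2] * e * e
    if (pred <= 0).any():
        raise ValueError("depth model predicts non-positive similarity on "
                         "training pairs; data too degenerate to normalize")
    cap = float(np.quantile(j / pred, cap_quantile))
    return DepthRegressionModel(beta0=float(beta[0]), beta1=float(beta[1]),
                                beta2=float(beta[2]), sample_size=size,
                                cap_value=cap)


def _fit_quadratic(j: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, bool]:
    if np.ptp(e) < 1e-15:
        return np.array([float(j.mean()), 0.0, 0.0]), True
    A = np.column_stack([np.ones_like(e), e, e * e])
    beta, *_ = np.linalg.lstsq(A, j, rcond=None)
    return beta, False


def normalize_jaccard(
    J: PairwiseSimilarity | np.ndarray,
    E: PairwiseSimilarity | np.ndarray,
    model: DepthRegressionModel,
    cap_quantile: float = 0.99,
) -> PairwiseSimilarity:
    """Divide observed by predicted Jaccard and cap outliers.

    N_ij = J_ij / (b0 + b1 E_ij + b2 E_ij^2); off-diagonal values above their
    ``cap_quantile`` quantile are capped at it, and the diagonal is set to the
    maximum off-diagonal value (keeping the kernel PSD-like without letting
    self-similarity dominate the quantile).
    """
    Jv = J.values if isinstance(J, PairwiseSimilarity) else np.asarray(J)
    Ev = E.values if isinstance(E, PairwiseSimilarity) else np.asarray(E)
    if Jv.shape != Ev.shape:
        raise ValueError("J and E must have the same shape")
    pred = model.predict(Ev)
    if (pred <= 0).any():
        i, j = np.unravel_index(int(np.argmin(pred)), pred.shape)
        raise ValueError(
            f"non-positive predicted similarity for pair ({i}, {j}): "
            f"pred={pred[i, j]:.3g}, beta={tuple(model.beta)}")
    N = Jv / pred
    off = ~np.eye(N.shape[0], dtype=bool)
    cap = float(np.quantile(N[off], cap_quantile))
    N = N.copy()
    N[off] = np.minimum(N[off], cap)
    np.fill_diagonal(N, N[off].max() if off.any() else cap)
    return PairwiseSimilarity(N, "normalized", cap=cap)


# ---------------------------------------------------------------------------
# spectral embedding


def spectral_embed(N: PairwiseSimilarity | np.ndarray, r: int) -> SpectralEmbedding:
    """Eigendecompose A = D^{-1/2} N D^{-1/2} and return the top-r eigenvectors.

    Eigenvalues are returned in descending order; each eigenvector's sign is
    fixed so that its largest-magnitude entry is positive.
    """
    Nv = N.values if isinstance(N, PairwiseSimilarity) else np.asarray(N, dtype=float)
    n = Nv.shape[0]
    if r >= n:
        raise ValueError(f"rank r={r} must be < n={n}")
    d = Nv.sum(axis=1)
    if (d <= 0).any():
        i = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"cell {i} has non-positive similarity row sum")
    dinv = 1.0 / np.sqrt(d)
    A = Nv * dinv[:, None] * dinv[None, :]
    A = (A + A.T) / 2.0
    evals, evecs = scipy.linalg.eigh(A, subset_by_index=[n - r, n - 1])
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    U = evecs[:, order]
    U = _fix_signs(U)
    return SpectralEmbedding(U=U, eigenvalues=evals, row_sums=d, r=r)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def select_dimensions(
    eigenvalues: np.ndarray,
    threshold: float = 2.0,
    override: int | None = None,
    bounds: tuple[int, int] = (2, 50),
) -> int:
    """Pick the embedding rank from the eigenvalue-gap profile.

    The manual practice is to inspect pairwise eigenvector scatter plots and
    stop where structure dissolves into a blob; the automated default returns
    the largest r whose gap lambda_r - lambda_{r+1} exceeds ``threshold``
    times the mean consecutive gap, clipped to ``bounds``. An explicit
    ``override`` is returned unchanged.
    """
    if override is not None:
        return int(override)
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 3:
        raise ValueError("need at least 3 eigenvalues")
    gaps = ev[:-1] - ev[1:]
    cut = gaps.mean() * threshold
    big = np.flatnonzero(gaps > cut)
    r = int(big[-1] + 1) if len(big) else bounds[0]
    return int(np.clip(r, bounds[0], min(bounds[1], len(ev) - 1)))


def embed(
    X: CellByBinMatrix,
    r: int,
    sample_size: int = 2000,
    seed: int = 1,
    depth_correct: bool = True,
) -> tuple[SpectralEmbedding, DepthRegressionModel | None]:
    """Full small-dataset pipeline: kernel, depth normalization, eigenvectors.

    With ``depth_correct=False`` the raw Jaccard kernel is embedded directly
    (the confounded baseline the normalization is evaluated against).
    """
    J = jaccard_matrix(X)
    if not depth_correct:
        return spectral_embed(J, r), None
    model = fit_depth_model(X, sample_size=sample_size, seed=seed)
    E = expected_jaccard(X.p)
    N = normalize_jaccard(J, E, model)
    return spectral_embed(N, r), model
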