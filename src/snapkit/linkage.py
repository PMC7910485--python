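"""Enhancer-gene linkage by logistic regression and differential-accessibility
scaffolding.

Linkage: for each ATAC cell a "pseudo-cell" expression profile is imputed as a
weighted average of its nearest RNA cells in a joint embedding. For a gene G,
every peak within a +/-1 Mb window of its TSS is regressed (logit link) on the
imputed expression Y^G; the slope's Wald p-value at the genome-wide 5e-8
cutoff calls a link. Distance-matched negative controls take, for each
positive pair, the peak on the opposite side of the TSS with the closest
absolute distance.

Differential accessibility: a cell group is compared against an equally sized
background of its nearest non-member cells (or the complement when the group
exceeds half the dataset). Counts are aggregated into two vectors and each
peak is tested with a negative-binomial exact test at fixed dispersion
bcv^2, conditioning on the peak's total count after library-size
normalization; Benjamini-Hochberg FDR < 0.05 calls significant peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import nbinom
from sklearn.metrics import pairwise_distances
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass
class PseudoCell:
    atac_cell: int
    imputed_expression: np.ndarray
    neighbor_ids: np.ndarray
    weights: np.ndarray


@dataclass
class LinkResult:
    gene: str
    peak: str
    distance: int
    beta1: float
    p_value: float
    significant: bool
    penalized: bool = False


@dataclass
class DARResult:
    peak: str
    log_fold_change: float
    p_value: float
    fdr: float = field(default=np.nan)

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05


# ---------------------------------------------------------------------------
# pseudo-cell imputation


def impute_expression(atac_coords: np.ndarray, rna_coords: np.ndarray,
                      expression: np.ndarray, k: int = 15,
                      uniform: bool = False) -> list[PseudoCell]:
    """Impute per-ATAC-cell expression from nearest RNA cells in a joint space.

    Weights are Gaussian in distance with bandwidth equal to the distance to
    the k-th neighbor (``uniform=True`` switches to equal weights), normalized
    to sum to 1.
    """
    atac_coords = np.atleast_2d(atac_coords)
    rna_coords = np.atleast_2d(rna_coords)
    expression = np.asarray(expression, dtype=float)
    k = min(k, len(rna_coords))
    d = pairwise_distances(atac_coords, rna_coords)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = []
    for i in range(len(atac_coords)):
        nbrs = order[i]
        dist = d[i, nbrs]
        if uniform or dist[-1] == 0:
            w = np.full(k, 1.0 / k)
        else:
            w = np.exp(-(dist / dist[-1]) ** 2)
            w = w / w.sum()
        out.append(PseudoCell(atac_cell=i,
                              imputed_expression=w @ expression[nbrs],
                              neighbor_ids=nbrs, weights=w))
    return out


# ---------------------------------------------------------------------------
# logistic linkage


def _ridge_logit(y: np.ndarray, x: np.ndarray, lam: float = 1e-4,
                 max_iter: int = 100):
    """Newton fit of a 2-parameter logistic with a small L2 penalty; returns
    (beta1, Wald p) from the penalized Hessian. Used when the unpenalized
    likelihood is unbounded (perfect separation)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - lam * beta
        H = X.T @ (X * w[:, None]) + lam * np.eye(2)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None]) + lam * np.eye(2)
    se = np.sqrt(np.linalg.inv(H)[1, 1])
    z = beta[1] / se
    from scipy.stats import norm

    return float(beta[1]), float(2 * norm.sf(abs(z)))


def link_gene(gene: str, imputed: np.ndarray, peak_states,
              peak_ids: list[str] | None = None,
              peak_distances: np.ndarray | None = None,
              window: int = 1_000_000,
              alpha: float = 5e-8) -> list[LinkResult]:
    """Test each candidate peak's binary state against imputed expression.

    ``peak_states`` is cells x peaks binary; peaks with a TSS distance beyond
    ``window`` are excluded when distances are given. Peaks that are all-0 or
    all-1 across cells are skipped (degenerate response). On perfect
    separation the slope and p come from a lightly penalized fit and the
    result is flagged ``penalized``.
    """
    imputed = np.asarray(imputed, dtype=float)
    P = np.asarray(sp.csr_matrix(peak_states).todense())
    n_peaks = P.shape[1]
    if peak_ids is None:
        peak_ids = [f"peak_{j}" for j in range(n_peaks)]
    if peak_distances is None:
        peak_distances = np.zeros(n_peaks, dtype=int)
    results = []
    X = sm.add_constant(imputed)
    for j in range(n_peaks):
        dist = int(peak_distances[j])
        if abs(dist) > window:
            continue
        y = P[:, j].astype(float)
        if y.min() == y.max():
            continue  # degenerate response
        beta1, p, penalized = _fit_logit(y, X, imputed)
        results.append(LinkResult(gene=gene, peak=peak_ids[j], distance=dist,
                                  beta1=beta1, p_value=p,
                                  significant=p < alpha, penalized=penalized))
    return results


def _fit_logit(y, X, x_raw):
    if np.ptp(x_raw) < 1e-12:
        return 0.0, 1.0, False  # constant predictor: no signal
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e6:
            raise PerfectSeparationError("unbounded slope")
        return float(fit.params[1]), float(fit.pvalues[1]), False
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        beta1, p = _ridge_logit(y, x_raw)
        return beta1, p, True


def negative_controls(positive_pairs: list[tuple[str, str, int]],
                      candidate_peaks: dict[str, list[tuple[str, int]]]
                      ) -> tuple[list[tuple[str, str, int]], int]:
    """Distance-matched controls on the opposite side of each gene's TSS.

    ``positive_pairs`` holds (gene, peak, signed TSS distance); for each the
    candidate peak of the same gene with opposite-signed distance minimizing
    | |d_pos| - |d_cand| | is chosen (ties toward smaller |distance|). Returns
    (matched pairs, number skipped for lack of an opposite-side peak).
    """
    matched, skipped = [], 0
    for gene, _peak, d_pos in positive_pairs:
        cands = [(pid, d) for pid, d in candidate_peaks.get(gene, [])
                 if d * d_pos < 0]
        if not cands:
            skipped += 1
            continue
        best = min(cands, key=lambda c: (abs(abs(d_pos) - abs(c[1])), abs(c[1])))
        matched.append((gene, best[0], best[1]))
    return matched, skipped


# ---------------------------------------------------------------------------
# differential accessibility


def select_background(cells_i: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Pick an equally sized background group of nearest non-member cells.

    If the group holds more than half of all cells the complement is used
    instead; otherwise the |C_i| non-members closest to the group centroid in
    the embedding are chosen.
    """
    cells_i = np.asarray(cells_i, dtype=int)
    n = len(embedding)
    if len(cells_i) == n:
        raise ValueError("group contains every cell; no background available")
    others = np.setdiff1d(np.arange(n), cells_i)
    if len(cells_i) > n / 2:
        return others
    centroid = np.asarray(embedding)[cells_i].mean(axis=0)
    d = np.linalg.norm(np.asarray(embedding)[others] - centroid, axis=1)
    order = np.argsort(d, kind="stable")
    return others[order[: len(cells_i)]]


def aggregate_counts(cells: np.ndarray, peak_counts) -> np.ndarray:
    """Column-sum the peak counts of a cell group into one raw-count vector."""
    cells = np.asarray(cells, dtype=int)
    if len(cells) == 0:
        raise ValueError("empty cell group")
    M = sp.csr_matrix(peak_counts)
    return np.asarray(M[cells].sum(axis=0)).ravel().astype(np.int64)


def _nb_exact_pvalue(y1: int, y2: int, dispersion: float) -> float:
    """Two-sided exact p for equal NB means given the sum, fixed dispersion.

    Conditional on s = y1 + y2, with both counts NB(mu, phi) at equal mu and
    phi, P(Y1 = y | s) is free of mu:
        P(y | s) = C(y + r - 1, y) C(s - y + r - 1, s - y) / C(s + 2r - 1, s)
    with r = 1/phi. The two-sided p doubles the smaller tail (capped at 1);
    for equal libraries the conditional distribution is symmetric, so this
    coincides with the minimum-likelihood convention.
    """
    s = y1 + y2
    if s == 0:
        return 1.0
    r = 1.0 / dispersion
    ys = np.arange(s + 1)
    # log of the conditional pmf via NB logpmf at an arbitrary p (cancels)
    logp = nbinom.logpmf(ys, r, 0.5) + nbinom.logpmf(s - ys, r, 0.5)
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    lower = pmf[: y1 + 1].sum()
    upper = pmf[y1:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def differential_test(V_ci: np.ndarray, V_cj: np.ndarray, bcv: float = 0.1,
                      peak_ids: list[str] | None = None) -> list[DARResult]:
    """Negative-binomial exact test per peak at fixed dispersion bcv^2.

    Both raw-count vectors are normalized to the common (geometric-mean)
    library size and rounded; each peak's p-value comes from the
    sum-conditioned NB enumeration, the log2 fold change from the normalized
    means (0.5 pseudocount), and FDR from Benjamini-Hochberg.
    """
    V_ci = np.asarray(V_ci, dtype=float)
    V_cj = np.asarray(V_cj, dtype=float)
    if V_ci.shape != V_cj.shape:
        raise ValueError("count vectors must have the same length")
    n1, n2 = V_ci.sum(), V_cj.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must have positive totals")
    common = float(np.sqrt(n1 * n2))
    y1 = np.rint(V_ci * (common / n1)).astype(np.int64)
    y2 = np.rint(V_cj * (common / n2)).astype(np.int64)
    dispersion = bcv * bcv
    if peak_ids is None:
        peak_ids = [f"peak_{j}" for j in range(len(V_ci))]
    results = []
    for j in range(len(V_ci)):
        if y1[j] == 0 and y2[j] == 0:
            results.append(DARResult(peak=peak_ids[j], log_fold_change=0.0,
                                     p_value=1.0))
            continue
        p = _nb_exact_pvalue(int(y1[j]), int(y2[j]), dispersion)
        lfc = float(np.log2((y1[j] + 0.5) / (y2[j] + 0.5)))
        results.append(DARResult(peak=peak_ids[j], log_fold_change=lfc,
                                 p_value=p))
    fdr = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def dar_table(results: list[DARResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "peak": [r.peak for r in results],
        "log_fold_change": [r.log_fold_change for r in results],
        "p_value": [r.p_value for r in results],
        "fdr": [r.fdr for r in results],
        "significant": [r.significant for r in results],
    })
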