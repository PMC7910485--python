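# Methods

## Overview

snapkit resolves cellular heterogeneity in single-cell ATAC-seq without
requiring a population-level peak list. Cells are represented as binary rows
over fixed-width genomic bins; similarity between cells is the Jaccard index
of their accessible-bin sets; the sequencing-depth component of that
similarity is regressed out; and the corrected kernel is embedded by a
normalized eigendecomposition. Landmark (Nystrom) extension makes the
embedding linear in the number of cells and doubles as the projection
machinery for reference-atlas label transfer.

## Preprocessing model

Fragments are BED-convention records (0-based, half-open) assumed already
deduplicated and transposase-shifted upstream. Filters, in order:

| step | rule | default |
|---|---|---|
| insert size | keep `min <= end - start <= max`, both inclusive | 50–1000 bp |
| barcode QC | unique fragments strictly `> min_fragments` AND promoter-overlap fraction within inclusive bounds | 1000; [0.2, 0.8] |
| binning | count a fragment once per bin it overlaps by >= 1 bp (midpoint assignment behind a flag) | 5 kb bins |
| trimming | zero the `ceil(nnz * f)` largest-count entries (suspected alignment artifacts), then set survivors to 1 | f = 0.001 over non-zero entries |
| bin filtering | drop blacklist-overlapping bins, chrX/chrY/chrM, and the top `floor(0.05 m)` bins by coverage — the last only when mean per-cell fragments >= 5000, since the coverage ranking is noise-dominated below that | |

Rounding conventions (ceil for trimming, floor for the top-coverage cut) and
the inclusive/strict bound choices are fixed for reproducibility; the counts
they act on are discrete, so any convention shifts results by at most one
entry or bin.

## Depth-corrected Jaccard embedding

For binary profiles x_i, x_j with per-bin signal probabilities
P_i = C_i / m (C_i the number of accessible bins), the observed Jaccard
J_ij = |x_i ∩ x_j| / |x_i ∪ x_j| is confounded by depth: for two *random*
profiles the expected intersection-over-union ratio is

    E_ij = P_i P_j / (P_i + P_j − P_i P_j),

monotone increasing in either P. The correction fits

    J_ij ≈ β0 + β1 E_ij + β2 E_ij²

by ordinary least squares over all pairs among a depth-balanced sample of
cells (default 2000; pairs with i = j are excluded because the diagonal
J = 1 carries no information and would bias the intercept), then rescales

    N_ij = J_ij / (β̂0 + β̂1 E_ij + β̂2 E_ij²),

capping values above the 0.99 quantile of the off-diagonal N and setting the
diagonal to the maximum off-diagonal value. The quadratic term absorbs the
saturation-driven curvature seen among high-coverage cells. A non-positive
predicted denominator is an error, not a clamp: it indicates the fit is
invalid for the data rather than a value to patch.

The balanced sample is drawn without replacement with probability
proportional to 1 / d(log10 C_i), where d is a Gaussian KDE (Scott's rule)
of the log-coverage distribution, so sparse regions of the depth
distribution stay represented.

The corrected kernel is symmetric-normalized, A = D^{-1/2} N D^{-1/2} with
D_ii = Σ_j N_ij, and eigendecomposed; the top-r eigenvectors (descending
eigenvalue, sign fixed so each column's largest-magnitude entry is positive)
form the embedding. Rank selection is manual in origin (inspect pairwise
eigenvector scatters until structure dissolves); the automated default takes
the largest r whose eigenvalue gap exceeds twice the mean consecutive gap,
clipped to [2, 50], and an explicit override always wins.

## Landmark extension and the ensemble

k landmark cells (default 10,000 at atlas scale) are drawn by the same
inverse-density sampling, their kernel N_kk embedded as above, and every
remaining cell v projected via

    A_vk = D_vv^{-1/2} N_vk D_kk^{-1/2},   U_vk = A_vk U_kk / Λ_kk,

with D_vv row sums taken against the landmarks and eigenvalues below 1e-12
excluded from the division (rank guard). Cross-pair similarities reuse the
landmark depth model and its cap; the query's P is computed on the shared
bin set. The stacked embedding is returned in the original cell order. The
n-by-n kernel is never materialized (O(nk) similarity storage).

Because a single landmark draw is stochastic, the ensemble variant runs p
experts (seeds derived as seed + j), builds the symmetrized binary KNN graph
of each expert embedding, and averages adjacencies with equal weight 1/p.
Community detection consumes the weighted consensus graph. Stacked-column
norms of the extension are not unity, so comparisons against full
embeddings in tests normalize columns (or compare subspaces) first.

## Clustering and metrics

KNN graphs are exact brute-force Euclidean neighbors with ties broken
toward the lower index, union-symmetrized. Community detection is a
pluggable contract: Leiden (RBConfiguration, leidenalg) is the default
because it accepts an explicit seed; Louvain (igraph multilevel) is
available and seeded through igraph's RNG. Labels are relabeled
contiguously from 0.

The connectivity index adds 1/i whenever a cell's i-th nearest neighbor
(i = 1..K, K = 15) carries a different label, summed over cells — zero iff
every neighborhood is label-pure; the unnormalized sum is reported, with
the per-cell mean available alongside since the normalization convention is
not standardized. Coverage entropy selects the top 10% of cells by
coverage, histograms them on a 50×50 grid spanning the bounding box of the
*whole* embedding, and reports Shannon entropy in nats. The full-embedding
box (rather than the subset's own box) is deliberate: it makes
concentration of deep cells in one corner of the embedding register as low
entropy, which is what the metric is for. ARI/NMI are the standard
pair-counting and (arithmetic-mean-normalized) information measures.

## Gene accessibility scores

G[i, j] counts fragments of cell i overlapping gene body j (>= 1 bp; a
fragment inside two overlapping genes counts for both). Rows are scaled to
counts-per-million, then smoothed by t = 3 steps of the Markov diffusion
G_hat = A^t G_cpm, where A is the row-normalized symmetrized KNN adjacency
with unit self-loops (self-loops keep a cell's own signal; row-stochasticity
is what makes the operator an average, hence the convexity bound
min G_cpm[:, j] <= G_hat[:, j] <= max G_cpm[:, j]). The scores guide cluster
annotation only; clusters are defined beforehand on the bin matrix.

## Reference projection and label transfer

Query cells binned on the reference's bin set are projected with the
landmark-extension formula (the similarity matrix, not the eigenvector
matrix, enters the degree normalization). In the joint space, mutual
5-nearest-neighbor reference-query pairs become anchors; queries with no
anchor are excluded and flagged. Anchors are scored by shared-neighbor
counts in the joint 30-NN graph, rescaled between the 0.01 and 0.90
quantiles and clipped to [0, 1] — the concrete shared-neighbor recipe is
isolated in one function so it can be swapped. Each query weights its
s = 50 nearest anchors (distances measured to the anchors' query-side
cells — the anchor-cell convention):

    D_ci = (1 − dist(c, a_i)/dist(c, a_s)) · S_ai       (s-th anchor: 0)
    D̃_ci = 1 − exp(−D_ci / (2/sd)²),  sd = 1  (the constant is 4, as printed)
    W_ci = D̃_ci / Σ_j D̃_cj.

Within the s nearest anchors dist(c, a_i) <= dist(c, a_s) by construction,
so D >= 0 holds without clamping. Label probabilities are P = W L with L
the anchors' one-hot reference labels; a query whose best probability falls
below 0.9 is flagged unassigned rather than forced. Replacing L with
reference 2-D coordinates transfers positions (a convex combination, so
inferred coordinates carry no metric meaning beyond the anchor hull).

## Enhancer-gene linkage and differential accessibility

Pseudo-cells: each ATAC cell's expression is the weighted average of its
k = 15 nearest RNA cells in a joint embedding (produced externally),
Gaussian weights with bandwidth equal to the k-th neighbor distance
(uniform weights behind a flag). For gene G, peaks within ±1 Mb of the TSS
are each regressed on the imputed expression with a logit link; the slope's
Wald p-value at 5e-8 calls a link. All-0/all-1 peaks are skipped; perfect
separation falls back to a ridge-penalized Newton fit (λ = 1e-4) whose
Wald p comes from the penalized Hessian, flagged in the result. No
covariates are included. Negative controls take, per positive pair, the
candidate peak on the opposite side of the TSS minimizing the absolute
distance difference (ties toward the smaller distance).

Differential accessibility compares a cell group against an equally sized
background: the complement if the group exceeds half the cells, otherwise
the group-size nearest non-members to the group centroid. Counts are
aggregated per group, normalized to the geometric-mean library size and
rounded, and each peak is tested with a negative-binomial exact test at
fixed dispersion bcv² (default bcv = 0.1): conditional on the peak's total
s, the count in group 1 follows the mu-free law
P(y | s) ∝ C(y+r−1, y) C(s−y+r−1, s−y) with r = 1/dispersion; the
two-sided p doubles the smaller tail (equal to the minimum-likelihood
convention under the equal-library symmetry). As dispersion → 0 this tends
to the binomial exact test. Benjamini-Hochberg FDR < 0.05 calls
significant peaks. The test is implemented in-package so the artifact is
self-contained and its dispersion convention is explicit.

## Synthetic data: what it emulates and what it does not

The generator mimics downsampling bulk profiles to single cells: each
population has per-bin rates (shared Gamma(shape 4, mean `base_rate`)
baseline plus `marker_boost`-fold elevation of its own disjoint 5% marker
bins), and each cell places a log-uniform 1,000–10,000 reads multinomially
over its population's rates — fixed per-cell depth, with depth spanning a
decade so it acts as a genuine confounder. Optional pieces: a rare
population at a given fraction of the dataset, binomial depth thinning, a
fragment-file rendering whose round trip through the matrix builder is
exact (fragments never cross bin edges), and a paired RNA program whose
genes are elevated in the population owning their assigned enhancer bin.

Defaults: 20,000 bins of 5 kb on one synthetic chromosome — a desk-scale
stand-in for the ~half-million genome-wide bins; heavier benchmark tests
use 10,000 bins and 1,500–5,000 cells to keep the default suite within
minutes on one core.

The moderate Gamma tail is a deliberate modeling boundary. With strongly
heavy-tailed rates (CV ≳ 1), binarization saturates hot bins and deep cells
acquire a genuinely different binary *profile*, not merely a larger
similarity scale; that component is invisible to any pairwise-similarity
rescaling, this package's included. Real tissues contain both effects, which
is why residual within-cluster depth gradients can survive normalization in
practice; passing the depth-correction tests here demonstrates removal of
the similarity-scale confounder, not immunity to saturation.

Other things the generator does not emulate: doublets, batch effects,
fragment-length structure, chromosome-level covariates, and within-
population continuous trajectories.

## Numerical and design notes

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); ensemble experts use seed + j; generators
  are byte-reproducible.
- Dense eigendecompositions (`scipy.linalg.eigh` on the top-r subset) are
  used throughout: desk-scale kernels are at most a few thousand cells, and
  the landmark block is k × k by design.
- Jaccard kernels densify the binary matrix to float32 for BLAS matmuls;
  memory is bounded by the landmark count at scale.
- Degenerate inputs fail loudly rather than silently: zero-coverage cells,
  zero similarity row sums, non-positive predicted similarities, empty
  graphs and empty groups are errors naming the offending cell or pair.
- A constant expected-Jaccard regression (all cells equal depth) falls back
  to β = (mean J, 0, 0) with a warning.
- The single-population depth benchmarks use `marker_boost = 1` (a
  homogeneous population has no marker contrast); multi-population
  benchmarks use the defaults.
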