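# snapkit

Peak-free analysis of single-cell ATAC-seq: depth-corrected Jaccard spectral
embedding of binary cell-by-bin matrices, landmark (Nystrom) scaling,
graph clustering, gene-accessibility scores, reference label transfer,
enhancer-gene linkage, and differential accessibility — with a
ground-truth simulator so everything is testable without downloads.

## Who this is for

Single-cell epigenomics analysts who want to cluster scATAC-seq cells
*before* any peak calling. Peak-dependent pipelines inherit whatever cell
types dominated the aggregate peak list; snapkit instead compares cells
directly on genome-wide fixed-width bins (default 5 kb), so rare
populations contribute to the representation from the start.

## The model

Cells are binary vectors over bins. Similarity is the Jaccard index
J_ij = |x_i ∩ x_j| / |x_i ∪ x_j|, which is strongly confounded by
sequencing depth: two unrelated cells with per-bin signal rates
P_i = C_i/m have expected overlap ratio

    E_ij = P_i P_j / (P_i + P_j − P_i P_j).

snapkit fits J ≈ β0 + β1 E + β2 E² on a depth-balanced cell sample and
rescales N_ij = J_ij / (β̂0 + β̂1 E_ij + β̂2 E_ij²) (0.99-quantile cap),
then embeds A = D^{−1/2} N D^{−1/2} by eigendecomposition. For large
datasets, k landmark cells drawn by inverse-density sampling are embedded
exactly and the remaining cells are projected onto their eigenbasis
(U_vk = A_vk U_kk / Λ_kk); an ensemble of p such draws averages the
experts' KNN graphs with weights 1/p for stable clustering. The same
extension projects query cells onto a reference atlas, where scored
mutual-nearest-neighbor anchors carry cluster labels to queries as
probabilities P = W L (cells below a 0.9 confidence are left unassigned).

Downstream: diffusion-smoothed gene-body CPM scores for annotation
(G_hat = A^t G, t = 3), logistic-regression enhancer–gene linkage at the
genome-wide 5e-8 cutoff with distance-matched negative controls, and a
negative-binomial exact test (fixed dispersion BCV² = 0.01) for
differential accessibility between a cell group and its matched
background. `docs/methods.md` has the full treatment.

## Worked example

Five simulated populations, 400 cells each, read depth log-uniform across
a full decade (1,000–10,000 reads/cell), embedded with 500 landmarks:

```python
import numpy as np
from snapkit import synthetic
from snapkit.core_matrix import binarize, drop_zero_coverage_cells
from snapkit.nystrom import nystrom_embed
from snapkit.graph import ari, cluster, knn_graph, connectivity_index

profiles = synthetic.make_profiles(n_pops=5, m_bins=10_000, seed=1)
ds = synthetic.simulate_cells(profiles, cells_per_pop=400,
                              coverage_range=(1000, 10_000), seed=1)
mat = drop_zero_coverage_cells(binarize(ds.counts))
print(f"matrix: {mat.n_cells} cells x {mat.n_bins} bins, "
      f"median coverage {int(np.median(mat.coverage))}")

U, model = nystrom_embed(mat, k=500, r=10, seed=1)
print(f"depth model beta = ({model.depth_model.beta0:.4f}, "
      f"{model.depth_model.beta1:.4f}, {model.depth_model.beta2:.4f})")

labels = cluster(knn_graph(U, k=15), resolution=0.5, seed=1)
print(f"{labels.n_clusters} clusters, ARI vs truth = "
      f"{ari(labels, ds.true_labels):.3f}, connectivity index = "
      f"{connectivity_index(U, labels, K=15):.2f}")
```

Output:

```
matrix: 2000 cells x 10000 bins, median coverage 2306
depth model beta = (0.0110, 1.1311, -0.0619)
6 clusters, ARI vs truth = 0.946, connectivity index = 30.65
```

Reading the numbers: the depth regression is close to J ≈ E (slope ~1.13
with a small negative curvature term — the saturation bend among deep
cells), clustering recovers the five planted populations almost exactly
(ARI 0.95; one population splits in two at this resolution), and the low
connectivity index (~0.015 per cell) says nearly every cell's 15 nearest
neighbors share its cluster.

The same steps are available from a shell via the `snapkit` CLI
(`snapkit simulate | qc | binmat | embed | nystrom | cluster | metrics |
gscore`), reading and writing fragment TSVs, MTX matrices and embedding
TSVs.

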