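"""Ground-truth synthetic scATAC-seq datasets for testing every module.

Emulates the bulk-downsampling simulation protocol: each population has a
bulk-like per-bin accessibility profile (shared baseline plus
population-specific boosted marker bins); single cells are drawn by placing a
fixed number of reads multinomially over the profile, with per-cell read
depth sampled log-uniformly across a decade (1,000-10,000 reads by default)
so that sequencing depth acts as a genuine confounder. Optional extras: a
rare spiked-in population, binomial depth thinning, a fragment-file
rendering for end-to-end matrix tests, and a paired RNA program with known
enhancer-gene links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_matrix import CellByBinCounts, FragmentSet, make_bins


@dataclass
class PopulationProfile:
    population: int
    probabilities: np.ndarray  # per-bin read placement probabilities, sum 1
    marker_bins: np.ndarray  # bins elevated only in this population


@dataclass
class SyntheticDataset:
    counts: CellByBinCounts
    true_labels: np.ndarray
    target_coverage: np.ndarray
    profiles: list[PopulationProfile] = field(default=None, repr=False)


def make_profiles(
    n_pops: int,
    m_bins: int = 20000,
    marker_fraction: float = 0.05,
    base_rate: float = 1.0,
    marker_boost: float = 8.0,
    seed: int = 1,
    rate_shape: float = 4.0,
) -> list[PopulationProfile]:
    """Build bulk-like population profiles with disjoint marker bins.

    A shared gamma baseline (shape ``rate_shape``, mean ``base_rate``) mimics
    the uneven coverage of real bulk profiles while keeping the rate tail
    moderate: with strongly heavy-tailed rates, binarization saturates the hot
    bins and turns sequencing depth into a genuine profile shift rather than a
    similarity-scale effect, which is outside what any pairwise-similarity
    normalization can correct (see the methods note). Each population elevates
    its own disjoint ``marker_fraction`` of bins by ``marker_boost``-fold.
    Probabilities are normalized per population.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    n_markers = int(marker_fraction * m_bins)
    if n_markers < 1:
        raise ValueError("marker_fraction * m_bins must be >= 1 per population")
    if n_pops * n_markers > m_bins:
        raise ValueError("marker bins exceed total bins; lower marker_fraction")
    rng = np.random.default_rng(seed)
    baseline = rng.gamma(rate_shape, base_rate / rate_shape, size=m_bins) + 1e-6
    marker_pool = rng.permutation(m_bins)[: n_pops * n_markers]
    profiles = []
    for p in range(n_pops):
        markers = np.sort(marker_pool[p * n_markers:(p + 1) * n_markers])
        rates = baseline.copy()
        rates[markers] *= marker_boost
        profiles.append(PopulationProfile(
            population=p, probabilities=rates / rates.sum(), marker_bins=markers))
    return profiles


def simulate_cells(
    profiles: list[PopulationProfile],
    cells_per_pop: int | list[int],
    coverage_range: tuple[int, int] = (1000, 10000),
    rare_pop_fraction: float = 0.0,
    seed: int = 1,
    bin_size: int = 5000,
    chrom: str = "chr1",
) -> SyntheticDataset:
    """Draw cells multinomially from their population profiles.

    Each cell's read count is sampled log-uniformly within ``coverage_range``
    and placed over the profile with one multinomial draw, mimicking
    downsampling of a bulk experiment to a fixed per-cell depth. With
    ``rare_pop_fraction > 0`` the last profile is treated as a rare spike-in
    population receiving ``round(rare_pop_fraction * n_base)`` cells, where
    n_base is the number of cells in the remaining populations. All bins are
    laid on one synthetic chromosome.
    """
    lo, hi = coverage_range
    if lo <= 0 or hi < lo:
        raise ValueError("coverage_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    if rare_pop_fraction > 0:
        base_profiles, rare_profile = profiles[:-1], profiles[-1]
    else:
        base_profiles, rare_profile = profiles, None
    if isinstance(cells_per_pop, int):
        cells_per_pop = [cells_per_pop] * len(base_profiles)
    if len(cells_per_pop) != len(base_profiles):
        raise ValueError("cells_per_pop length must match the base populations")
    n_base = int(sum(cells_per_pop))
    plan = list(zip(base_profiles, cells_per_pop))
    if rare_profile is not None:
        n_rare = int(round(rare_pop_fraction * n_base))
        plan.append((rare_profile, n_rare))

    m = len(profiles[0].probabilities)
    blocks, labels, coverages = [], [], []
    for prof, n_cells in plan:
        if n_cells == 0:
            continue
        cov = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))
        cov = np.round(cov).astype(np.int64)
        counts = rng.multinomial(cov, prof.probabilities)
        blocks.append(sp.csr_matrix(counts))
        labels.append(np.full(n_cells, prof.population))
        coverages.append(cov)
    counts = sp.vstack(blocks).tocsr()
    labels = np.concatenate(labels)
    coverages = np.concatenate(coverages)
    barcodes = [f"cell_{i:06d}" for i in range(counts.shape[0])]
    bin_coords = make_bins({chrom: m * bin_size}, bin_size)
    cbb = CellByBinCounts(counts=counts, cell_barcodes=barcodes,
                          bin_coords=bin_coords, bin_size=bin_size)
    return SyntheticDataset(counts=cbb, true_labels=labels,
                            target_coverage=coverages, profiles=list(profiles))


def perturb_depth(dataset: SyntheticDataset, keep_fraction: float = 0.9,
                  seed: int = 1) -> SyntheticDataset:
    """Binomially thin every count at ``keep_fraction`` (labels preserved)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    X = dataset.counts.counts.tocsr(copy=True)
    if keep_fraction < 1:
        rng = np.random.default_rng(seed)
        X.data = rng.binomial(X.data, keep_fraction)
        X.eliminate_zeros()
    cbb = CellByBinCounts(counts=X, cell_barcodes=list(dataset.counts.cell_barcodes),
                          bin_coords=dataset.counts.bin_coords,
                          bin_size=dataset.counts.bin_size)
    return SyntheticDataset(counts=cbb, true_labels=dataset.true_labels.copy(),
                            target_coverage=dataset.target_coverage.copy(),
                            profiles=dataset.profiles)


def render_fragments(dataset: SyntheticDataset, frag_len: int = 200,
                     seed: int = 1) -> FragmentSet:
    """Emit one fragment per count, placed so no fragment crosses a bin edge.

    Round-tripping through the bin-matrix builder therefore reproduces the
    count matrix exactly. Fragment starts are uniform within
    [bin_start, bin_end - frag_len].
    """
    cbb = dataset.counts
    if frag_len >= cbb.bin_size:
        raise ValueError("frag_len must be smaller than bin_size")
    rng = np.random.default_rng(seed)
    X = cbb.counts.tocoo()
    reps = X.data.astype(np.int64)
    cell_idx = np.repeat(X.row, reps)
    bin_idx = np.repeat(X.col, reps)
    bins = cbb.bin_coords
    bstart = bins["start"].to_numpy()[bin_idx]
    bend = bins["end"].to_numpy()[bin_idx]
    span = np.maximum(bend - bstart - frag_len, 1)
    starts = bstart + rng.integers(0, span)
    ends = starts + frag_len
    chroms = bins["chrom"].to_numpy()[bin_idx]
    barcodes = np.asarray(cbb.cell_barcodes)[cell_idx]
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                       "barcode": barcodes})
    df = df.sort_values("barcode", kind="stable").reset_index(drop=True)
    chrom_sizes = (bins.groupby("chrom")["end"].max()).to_dict()
    return FragmentSet(records=df, chrom_sizes=chrom_sizes)


@dataclass
class PairedRNA:
    expression: np.ndarray  # rna cells x genes
    rna_labels: np.ndarray
    gene_ids: list[str]
    true_links: list[tuple[int, int]]  # (gene index, enhancer bin index)
    enhancer_bins: np.ndarray


def simulate_paired_rna(
    profiles: list[PopulationProfile],
    n_rna_cells: int,
    n_genes: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 1,
) -> PairedRNA:
    """Generate a paired RNA program with known enhancer-gene links.

    Each gene is linked to one marker bin of one population; its mean
    log-expression is elevated by ``effect_size`` in that population, so the
    gene's expression co-varies with the accessibility of its enhancer bin
    across populations. ``effect_size = 0`` produces no true links (empty
    truth table). Expression is log-normal with ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    n_pops = len(profiles)
    gene_ids = [f"gene_{g}" for g in range(n_genes)]
    gene_pop = rng.integers(0, n_pops, size=n_genes)
    enhancer_bins = np.array([
        rng.choice(profiles[p].marker_bins) for p in gene_pop])
    rna_labels = rng.integers(0, n_pops, size=n_rna_cells)
    base = np.full((n_pops, n_genes), 1.0)
    if effect_size > 0:
        base[gene_pop, np.arange(n_genes)] += effect_size
    log_expr = base[rna_labels] + rng.normal(0, noise_sd, size=(n_rna_cells, n_genes))
    true_links = ([(g, int(enhancer_bins[g])) for g in range(n_genes)]
                  if effect_size > 0 else [])
    return PairedRNA(expression=np.exp(log_expr), rna_labels=rna_labels,
                     gene_ids=gene_ids, true_links=true_links,
                     enhancer_bins=enhancer_bins)
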