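"""Gene-body accessibility scores: counting, CPM normalization, diffusion.

Cluster annotation works off a cells-by-genes matrix G where G[i, j] counts
fragments of cell i overlapping gene body j. After counts-per-million row
normalization, the score is smoothed over the cell-cell KNN graph by a
Markov diffusion, G_hat = A^t G_cpm, where A is the row-stochastic
transition matrix (symmetrized KNN adjacency plus self loops, rows
normalized) acting on cells and t the number of steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .core_matrix import FragmentSet
from .graph import KNNGraph


@dataclass
class GeneScoreMatrix:
    raw: sp.csr_matrix
    gene_ids: list[str]
    cell_barcodes: list[str]
    cpm: sp.csr_matrix | None = field(default=None)
    smoothed: np.ndarray | None = field(default=None)


def build_gene_matrix(frags: FragmentSet, genes: pd.DataFrame,
                      barcodes: list[str] | None = None) -> GeneScoreMatrix:
    """Count fragments per (cell, gene body) with the >=1 bp overlap rule.

    ``genes`` is a BED-like frame with columns chrom, start, end, name; gene
    intervals may overlap each other, in which case a fragment is counted once
    for every gene it overlaps.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene set")
    gene_ids = [str(g) for g in genes["name"]]
    trees: dict[str, IntervalTree] = {}
    for gi, row in enumerate(genes.itertuples(index=False)):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), gi)

    df = frags.records
    if barcodes is None:
        barcodes = sorted(df["barcode"].unique())
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    rows, cols = [], []
    for chrom, start, end, barcode in zip(df["chrom"], df["start"], df["end"],
                                          df["barcode"]):
        ci = bc_idx.get(barcode)
        tree = trees.get(chrom)
        if ci is None or tree is None:
            continue
        for iv in tree.overlap(start, end):
            rows.append(ci)
            cols.append(iv.data)
    raw = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(barcodes), len(gene_ids))).tocsr()
    raw.sum_duplicates()
    return GeneScoreMatrix(raw=raw, gene_ids=gene_ids, cell_barcodes=list(barcodes))


def cpm(raw: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Scale each cell's gene counts to sum to one million.

    All-zero rows stay zero (with a warning): no gene-overlapping fragment
    means there is nothing to normalize.
    """
    X = sp.csr_matrix(raw, dtype=np.float64)
    sums = np.asarray(X.sum(axis=1)).ravel()
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have no gene-overlapping "
                      "fragments; their CPM rows stay zero")
    scale = np.divide(1e6, sums, out=np.zeros_like(sums), where=~zero)
    return sp.diags(scale) @ X


def diffusion_operator(graph: KNNGraph | sp.spmatrix) -> sp.csr_matrix:
    """Row-stochastic transition matrix from a KNN graph with self loops."""
    adj = graph.adjacency if isinstance(graph, KNNGraph) else sp.csr_matrix(graph)
    adj = adj.maximum(adj.T) + sp.eye(adj.shape[0], format="csr")
    rowsum = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(1.0 / rowsum) @ adj).tocsr()


def diffuse(cpm_matrix: sp.spmatrix | np.ndarray,
            graph: KNNGraph | sp.spmatrix, t: int = 3) -> np.ndarray:
    """Smooth CPM scores by t steps of the Markov diffusion, G_hat = A^t G.

    Computed as (A (A G)) ... to avoid densifying A^t. t = 0 returns the
    input unchanged.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    G = np.asarray(sp.csr_matrix(cpm_matrix).todense(), dtype=np.float64)
    if t == 0:
        return G
    A = diffusion_operator(graph)
    # each step replaces a cell's score by the stochastic average over its
    # neighborhood (cells are rows of G, so A acts from the left)
    out = G
    for _ in range(t):
        out = A @ out
    return out


def gene_scores(frags: FragmentSet, genes: pd.DataFrame,
                graph: KNNGraph, t: int = 3,
                barcodes: list[str] | None = None) -> GeneScoreMatrix:
    """End-to-end gene accessibility scores: count, CPM, diffuse."""
    gm = build_gene_matrix(frags, genes, barcodes=barcodes)
    gm.cpm = cpm(gm.raw)
    gm.smoothed = diffuse(gm.cpm, graph, t=t)
    return gm
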