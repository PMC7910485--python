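"""Fragment ingestion, barcode QC and construction of the binary cell-by-bin matrix.

The pipeline entry point: tab-separated fragment records (chrom, start, end,
barcode; BED-style 0-based half-open coordinates) are filtered by insert size,
barcodes are retained by unique-fragment count and promoter-overlap ratio, the
genome is tiled into uniform bins, fragment-bin overlaps are counted, the count
matrix is trimmed of its highest-count entries and binarized, and uninformative
bins (blacklist, sex/mitochondrial chromosomes, top-coverage) are removed.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]

#: chromosomes removed by default during bin filtering (sex effect, mtDNA)
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX", "chrY", "chrM"})


class FragmentParseError(ValueError):
    """A fragment record could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass
class FragmentSet:
    """Deduplicated, insert-filtered fragments with their genome's chrom sizes.

    ``records`` is a DataFrame with columns chrom, start, end, barcode sorted
    by barcode; coordinates are 0-based half-open and satisfy
    0 <= start < end <= chrom length.
    """

    records: pd.DataFrame
    chrom_sizes: dict[str, int]
    n_rejected: int = 0
    n_unknown_chrom: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def barcodes(self) -> np.ndarray:
        return self.records["barcode"].unique()


@dataclass
class BarcodeQC:
    barcode: str
    n_fragments: int
    promoter_fraction: float
    passed: bool


@dataclass
class CellByBinCounts:
    """Non-negative fragment counts per (cell, genomic bin).

    Bins tile each chromosome contiguously at ``bin_size`` (the last bin of a
    chromosome is truncated to the chromosome end).
    """

    counts: sp.csr_matrix
    cell_barcodes: list[str]
    bin_coords: pd.DataFrame  # columns chrom, start, end
    bin_size: int


@dataclass
class CellByBinMatrix:
    """Binary accessibility matrix with per-cell coverage C_i and P_i = C_i/m."""

    X: sp.csr_matrix
    cell_barcodes: list[str]
    bin_coords: pd.DataFrame
    coverage: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)
    kept_bins: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.coverage is None:
            self._recompute()
        if self.kept_bins is None:
            self.kept_bins = np.ones(self.X.shape[1], dtype=bool)

    def _recompute(self):
        self.coverage = np.asarray(self.X.sum(axis=1)).ravel()
        self.p = self.coverage / self.X.shape[1]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# fragment I/O


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column (chrom, length) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     usecols=[0, 1])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    """Read the first len(names) columns of a BED file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(len(names)))
    df.columns = list(names)
    return df


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(
    path,
    chrom_sizes: dict[str, int],
    min_insert: int = 50,
    max_insert: int = 1000,
) -> FragmentSet:
    """Parse a 4+ column fragment TSV and apply the insert-size filter.

    Only fragments with ``min_insert <= end - start <= max_insert`` (both
    inclusive) are kept. Records with start >= end are rejected and counted;
    fragments on chromosomes absent from ``chrom_sizes`` are dropped with a
    logged count. Raises :class:`FragmentParseError` (with the offending
    1-based line number) on malformed lines.
    """
    chroms, starts, ends, barcodes = [], [], [], []
    n_rejected = 0
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FragmentParseError(lineno, f"expected >=4 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentParseError(lineno, f"non-integer coordinate: {exc}") from None
            if not parts[3]:
                raise FragmentParseError(lineno, "empty barcode")
            if start >= end or start < 0:
                n_rejected += 1
                continue
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            barcodes.append(parts[3])

    df = pd.DataFrame({
        "chrom": pd.Series(chroms, dtype=str),
        "start": pd.Series(starts, dtype=np.int64),
        "end": pd.Series(ends, dtype=np.int64),
        "barcode": pd.Series(barcodes, dtype=str),
    })
    return filter_fragments(df, chrom_sizes, min_insert, max_insert, n_rejected)


def filter_fragments(
    df: pd.DataFrame,
    chrom_sizes: dict[str, int],
    min_insert: int = 50,
    max_insert: int = 1000,
    n_rejected: int = 0,
) -> FragmentSet:
    """Apply chromosome and insert-size filters to an in-memory fragment frame."""
    known = df["chrom"].isin(chrom_sizes)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("dropped %d fragments on chromosomes absent from chrom_sizes",
                       n_unknown)
    df = df[known]
    # clip check: fragments must lie within the chromosome
    sizes = df["chrom"].map(chrom_sizes)
    in_bounds = df["end"] <= sizes
    n_rejected += int((~in_bounds).sum())
    df = df[in_bounds]
    length = df["end"] - df["start"]
    df = df[(length >= min_insert) & (length <= max_insert)]
    df = df.sort_values("barcode", kind="stable").reset_index(drop=True)
    return FragmentSet(records=df, chrom_sizes=dict(chrom_sizes),
                       n_rejected=n_rejected, n_unknown_chrom=n_unknown)


# ---------------------------------------------------------------------------
# interval overlap helpers (merged, sorted, non-overlapping intervals)


def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge BED intervals per chromosome into sorted disjoint (starts, ends)."""
    out = {}
    for chrom, grp in df.groupby("chrom"):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[str(chrom)] = (np.asarray(starts, dtype=np.int64),
                           np.asarray(ends, dtype=np.int64))
    return out


def _overlaps_any(starts: np.ndarray, ends: np.ndarray,
                  merged: dict[str, tuple[np.ndarray, np.ndarray]],
                  chroms: np.ndarray) -> np.ndarray:
    """Vectorized >=1 bp overlap of half-open [start, end) against merged intervals."""
    hit = np.zeros(len(starts), dtype=bool)
    chroms = np.asarray(chroms)
    for chrom in np.unique(chroms):
        if chrom not in merged:
            continue
        mstarts, mends = merged[chrom]
        mask = chroms == chrom
        s, e = starts[mask], ends[mask]
        # candidate = last interval with mstart < e; overlap iff its mend > s
        idx = np.searchsorted(mstarts, e, side="left") - 1
        ok = idx >= 0
        cand_end = np.where(ok, mends[np.clip(idx, 0, None)], 0)
        hit[np.flatnonzero(mask)] = ok & (cand_end > s)
    return hit


# ---------------------------------------------------------------------------
# barcode QC


def qc_barcodes(
    frags: FragmentSet,
    promoters: pd.DataFrame,
    min_fragments: int = 1000,
    promoter_range: tuple[float, float] = (0.2, 0.8),
) -> list[BarcodeQC]:
    """Score each barcode by fragment count and promoter-overlap ratio.

    A barcode passes iff its unique-fragment count is strictly greater than
    ``min_fragments`` and the fraction of its fragments overlapping at least
    one promoter interval by >= 1 bp lies within ``promoter_range`` (bounds
    inclusive).
    """
    df = frags.records
    if df.empty:
        return []
    merged = _merge_intervals(promoters)
    in_promoter = _overlaps_any(df["start"].to_numpy(), df["end"].to_numpy(),
                                merged, df["chrom"].to_numpy())
    tmp = pd.DataFrame({"barcode": df["barcode"].to_numpy(), "hit": in_promoter})
    agg = tmp.groupby("barcode", sort=True)["hit"].agg(["size", "mean"])
    lo, hi = promoter_range
    out = []
    for barcode, (n, frac) in agg.iterrows():
        n = int(n)
        passed = (n > min_fragments) and (lo <= frac <= hi)
        out.append(BarcodeQC(barcode=str(barcode), n_fragments=n,
                             promoter_fraction=float(frac), passed=passed))
    return out


# ---------------------------------------------------------------------------
# cell-by-bin matrix


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Tile every chromosome with contiguous 0-based half-open bins."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def build_bin_matrix(
    frags: FragmentSet,
    bin_size: int = 5000,
    barcodes: list[str] | None = None,
    midpoint: bool = False,
) -> CellByBinCounts:
    """Count fragment-bin overlaps into a sparse cells-by-bins matrix.

    counts[i, j] is the number of fragments of cell i overlapping bin j by
    >= 1 bp; a fragment spanning a bin boundary increments every bin it
    touches. With ``midpoint=True`` a fragment is instead assigned only to the
    bin containing its midpoint. Bins are 0-based half-open
    [k*bin_size, (k+1)*bin_size), truncated at the chromosome end. Cells are
    the rows, ordered as in ``barcodes`` (barcodes absent from the fragments
    yield all-zero rows with a warning); with ``barcodes=None`` every barcode
    present is used, in sorted order.
    """
    bins = make_bins(frags.chrom_sizes, bin_size)
    # global bin index: offset per chromosome
    offsets = {}
    off = 0
    nbins_per_chrom = {}
    for chrom, size in frags.chrom_sizes.items():
        offsets[chrom] = off
        nbins_per_chrom[chrom] = int(np.ceil(size / bin_size)) if size > 0 else 0
        off += nbins_per_chrom[chrom]
    m = off

    df = frags.records
    if barcodes is None:
        barcodes = sorted(df["barcode"].unique())
    barcode_idx = {b: i for i, b in enumerate(barcodes)}
    present = df["barcode"].isin(barcode_idx)
    missing = set(barcodes) - set(df["barcode"].unique())
    if missing:
        warnings.warn(f"{len(missing)} barcodes in pass-list have no fragments; "
                      "rows are all-zero")
    df = df[present]
    n = len(barcodes)
    if df.empty:
        return CellByBinCounts(sp.csr_matrix((n, m), dtype=np.int64),
                               list(barcodes), bins, bin_size)

    rows_cells = df["barcode"].map(barcode_idx).to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chrom_off = df["chrom"].map(offsets).to_numpy()
    if midpoint:
        mid = (starts + ends) // 2
        cell_idx = rows_cells
        bin_idx = chrom_off + mid // bin_size
    else:
        first = starts // bin_size
        last = (ends - 1) // bin_size
        nb = (last - first + 1).astype(np.int64)
        cell_idx = np.repeat(rows_cells, nb)
        # grouped arange: bin offsets within each fragment
        total = int(nb.sum())
        within = np.arange(total) - np.repeat(np.cumsum(nb) - nb, nb)
        bin_idx = np.repeat(chrom_off + first, nb) + within
    counts = sp.coo_matrix(
        (np.ones(len(cell_idx), dtype=np.int64), (cell_idx, bin_idx)),
        shape=(n, m),
    ).tocsr()
    counts.sum_duplicates()
    return CellByBinCounts(counts, list(barcodes), bins, bin_size)


def binarize(counts: CellByBinCounts, top_fraction: float = 0.001) -> CellByBinMatrix:
    """Zero out the highest-count entries, then binarize the remainder.

    Entries with abnormally high counts are commonly alignment artifacts; the
    ``ceil(nnz * top_fraction)`` non-zero entries with the largest counts (ties
    broken toward the larger count, then stable order) are set to 0 and every
    other non-zero entry becomes 1.
    """
    if not 0 <= top_fraction < 1:
        raise ValueError("top_fraction must be in [0, 1)")
    X = counts.counts.tocsr(copy=True)
    X.eliminate_zeros()
    z = X.nnz
    if z == 0:
        return CellByBinMatrix(X.astype(np.int8), list(counts.cell_barcodes),
                               counts.bin_coords.copy())
    n_trim = int(np.ceil(z * top_fraction))
    if n_trim > 0:
        order = np.argsort(-X.data, kind="stable")
        X.data[order[:n_trim]] = 0
    X.data = (X.data > 0).astype(np.int8)
    X.eliminate_zeros()
    return CellByBinMatrix(X, list(counts.cell_barcodes), counts.bin_coords.copy())


def filter_bins(
    mat: CellByBinMatrix,
    blacklist: pd.DataFrame | None = None,
    exclude_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDE_CHROMS,
    top_coverage_fraction: float = 0.05,
    low_coverage_skip: float = 5000,
) -> CellByBinMatrix:
    """Remove blacklist/excluded-chromosome bins and the most invariant bins.

    The top ``top_coverage_fraction`` of remaining bins by column sum
    (floor rounding) are removed only when the mean per-cell fragment count is
    at least ``low_coverage_skip``; for shallower data the coverage ranking is
    noise-dominated and the filter is skipped.
    """
    bins = mat.bin_coords
    keep = ~bins["chrom"].isin(set(exclude_chroms)).to_numpy()
    if blacklist is not None and len(blacklist):
        merged = _merge_intervals(blacklist)
        bad = _overlaps_any(bins["start"].to_numpy(), bins["end"].to_numpy(),
                            merged, bins["chrom"].to_numpy())
        keep &= ~bad
    mean_cov = float(mat.coverage.mean()) if mat.n_cells else 0.0
    if mean_cov >= low_coverage_skip and top_coverage_fraction > 0:
        colsum = np.asarray(mat.X.sum(axis=0)).ravel()
        remaining = np.flatnonzero(keep)
        n_drop = int(np.floor(top_coverage_fraction * len(remaining)))
        if n_drop > 0:
            order = remaining[np.argsort(-colsum[remaining], kind="stable")]
            keep[order[:n_drop]] = False
    if not keep.any():
        raise ValueError("no features remain after bin filtering")
    kept_bins = mat.kept_bins.copy()
    kept_bins[np.flatnonzero(mat.kept_bins)] = keep
    out = CellByBinMatrix(
        X=mat.X[:, keep].tocsr(),
        cell_barcodes=list(mat.cell_barcodes),
        bin_coords=bins[keep].reset_index(drop=True),
        kept_bins=kept_bins,
    )
    return out


def drop_zero_coverage_cells(mat: CellByBinMatrix) -> CellByBinMatrix:
    """Remove cells with no accessible bins (required before Jaccard kernels)."""
    keep = mat.coverage > 0
    if keep.all():
        return mat
    return CellByBinMatrix(
        X=mat.X[keep].tocsr(),
        cell_barcodes=[b for b, k in zip(mat.cell_barcodes, keep) if k],
        bin_coords=mat.bin_coords,
        kept_bins=mat.kept_bins,
    )
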