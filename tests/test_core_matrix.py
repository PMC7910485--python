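"""Fragment parsing, barcode QC, bin-matrix construction, binarization, filtering."""

import numpy as np
import pandas as pd
import pytest

from snapkit.core_matrix import (
    CellByBinMatrix,
    FragmentParseError,
    binarize,
    build_bin_matrix,
    filter_bins,
    filter_fragments,
    qc_barcodes,
    read_fragments,
)

from conftest import counts_from_dense, write_fragments_file

CHROMS = {"chr1": 100_000, "chr2": 50_000}


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"])


class TestReadFragments:
    @pytest.mark.parametrize("length,kept", [
        (49, False),   # below the inclusive lower bound
        (50, True),
        (1000, True),
        (1001, False),
    ])
    def test_insert_size_bounds_inclusive(self, tmp_path, length, kept):
        path = write_fragments_file(tmp_path, [("chr1", 100, 100 + length, "AA")])
        fs = read_fragments(path, CHROMS)
        assert len(fs) == (1 if kept else 0)

    def test_survivor_count(self, tmp_path):
        rows = [("chr1", i * 10, i * 10 + 100, "AA") for i in range(7)]
        rows += [("chr1", 0, 2000, "BB")] * 3
        path = write_fragments_file(tmp_path, rows)
        fs = read_fragments(path, CHROMS)
        assert len(fs) == 7

    def test_malformed_line_reports_number(self, tmp_path):
        path = write_fragments_file(
            tmp_path, [("chr1", 0, 100, "AA"), ("chr1", "oops", 100, "BB")])
        with pytest.raises(FragmentParseError, match="line 2"):
            read_fragments(path, CHROMS)

    def test_inverted_coordinates_rejected_and_counted(self, tmp_path):
        path = write_fragments_file(
            tmp_path, [("chr1", 500, 100, "AA"), ("chr1", 0, 100, "AA")])
        fs = read_fragments(path, CHROMS)
        assert len(fs) == 1
        assert fs.n_rejected == 1

    def test_unknown_chromosome_dropped_with_count(self, tmp_path):
        path = write_fragments_file(
            tmp_path, [("chrUn", 0, 100, "AA"), ("chr1", 0, 100, "AA")])
        fs = read_fragments(path, CHROMS)
        assert len(fs) == 1
        assert fs.n_unknown_chrom == 1

    def test_records_sorted_by_barcode(self, tmp_path):
        path = write_fragments_file(
            tmp_path, [("chr1", 0, 100, "ZZ"), ("chr1", 0, 100, "AA")])
        fs = read_fragments(path, CHROMS)
        assert list(fs.records["barcode"]) == ["AA", "ZZ"]


class TestQCBarcodes:
    def make_frags(self, per_barcode):
        """per_barcode: {barcode: (n_fragments, n_in_promoter)} on chr1;
        promoter fixture covers chr1:[1000,2000)."""
        rows = []
        for bc, (n, n_prom) in per_barcode.items():
            for i in range(n_prom):
                start = 1000 + (i % 900)
                rows.append(("chr1", start, start + 100, bc))
            for i in range(n - n_prom):
                rows.append(("chr1", 10_000 + i, 10_100 + i, bc))
        return filter_fragments(frame(rows), CHROMS)

    def test_fragment_count_bound_is_strict(self, promoters_bed):
        frags = self.make_frags({"A": (1000, 500), "B": (1001, 500)})
        res = {r.barcode: r for r in qc_barcodes(frags, promoters_bed)}
        assert not res["A"].passed  # exactly 1000 fails the strict > bound
        assert res["B"].passed

    @pytest.mark.parametrize("n_prom,expect", [
        (1000, True),   # fraction 0.5
        (1800, False),  # fraction 0.9, above the inclusive upper bound
        (200, False),   # fraction 0.1
        (400, True),    # fraction 0.2, inclusive lower bound
    ])
    def test_promoter_fraction_bounds(self, promoters_bed, n_prom, expect):
        frags = self.make_frags({"A": (2000, n_prom)})
        (r,) = qc_barcodes(frags, promoters_bed)
        assert r.promoter_fraction == pytest.approx(n_prom / 2000)
        assert r.passed is expect

    def test_single_bp_overlap_counts(self, promoters_bed):
        # fragment [999, 1001) overlaps promoter [1000, 2000) by 1 bp
        frags = filter_fragments(frame([("chr1", 940, 1001, "A")]), CHROMS)
        (r,) = qc_barcodes(frags, promoters_bed, min_fragments=0)
        assert r.promoter_fraction == 1.0

    def test_empty_fragments_give_empty_result(self, promoters_bed):
        frags = filter_fragments(frame([]), CHROMS)
        assert qc_barcodes(frags, promoters_bed) == []

    def test_order_invariant_over_fragments(self, promoters_bed):
        frags = self.make_frags({"A": (1200, 600), "B": (1500, 400)})
        shuffled = filter_fragments(
            frags.records.sample(frac=1, random_state=0), CHROMS)
        a = [(r.barcode, r.n_fragments, r.promoter_fraction, r.passed)
             for r in qc_barcodes(frags, promoters_bed)]
        b = [(r.barcode, r.n_fragments, r.promoter_fraction, r.passed)
             for r in qc_barcodes(shuffled, promoters_bed)]
        assert a == b


class TestBuildBinMatrix:
    def build(self, rows, **kw):
        frags = filter_fragments(frame(rows), CHROMS)
        return build_bin_matrix(frags, **kw)

    def test_fragment_within_one_bin(self):
        cbb = self.build([("chr1", 0, 100, "A")], bin_size=5000)
        row = cbb.counts[0].toarray().ravel()
        assert row[0] == 1 and row.sum() == 1

    def test_boundary_spanning_fragment_hits_both_bins(self):
        cbb = self.build([("chr1", 4900, 5100, "A")], bin_size=5000)
        row = cbb.counts[0].toarray().ravel()
        assert row[0] == 1 and row[1] == 1 and row.sum() == 2

    def test_midpoint_mode_assigns_single_bin(self):
        frags = filter_fragments(frame([("chr1", 4900, 5100, "A")]), CHROMS)
        cbb = build_bin_matrix(frags, bin_size=5000, midpoint=True)
        assert cbb.counts.sum() == 1
        assert cbb.counts[0, 1] == 1  # midpoint 5000 falls in bin 1

    def test_missing_barcode_gives_zero_row(self):
        with pytest.warns(UserWarning, match="no fragments"):
            cbb = self.build([("chr1", 0, 100, "A")], bin_size=5000,
                             barcodes=["A", "GHOST"])
        assert cbb.counts[1].nnz == 0

    def test_fragment_conservation(self, rng):
        rows = []
        for i in range(50):
            start = int(rng.integers(0, 90_000))
            rows.append(("chr1", start, start + int(rng.integers(50, 900)),
                         f"bc{i % 5}"))
        cbb = self.build(rows, bin_size=1000)
        assert cbb.counts.sum() >= 50  # each fragment counted >= once

    def test_bins_tile_chromosomes_with_truncated_last(self):
        cbb = self.build([("chr1", 0, 100, "A")], bin_size=30_000)
        chr1 = cbb.bin_coords[cbb.bin_coords["chrom"] == "chr1"]
        assert list(chr1["start"]) == [0, 30_000, 60_000, 90_000]
        assert list(chr1["end"])[-1] == 100_000  # truncated


class TestBinarize:
    def test_top_entry_zeroed(self, rng):
        # 1000 non-zero entries, one of count 500: top 0.1% = 1 entry zeroed
        dense = np.zeros((10, 100), dtype=int)
        idx = rng.permutation(1000)
        dense.flat[idx] = 1
        dense.flat[idx[0]] = 500
        mat = binarize(counts_from_dense(dense), top_fraction=0.001)
        assert mat.X.nnz == 999
        assert mat.X.toarray().flat[idx[0]] == 0

    def test_ceil_rounding_on_small_matrices(self):
        dense = np.zeros((2, 10), dtype=int)
        dense[0, :5] = [5, 4, 3, 2, 1]
        dense[1, :5] = [1, 1, 1, 1, 1]
        mat = binarize(counts_from_dense(dense), top_fraction=0.001)
        # ceil(10 * 0.001) = 1 entry (the count-5 one) zeroed
        assert mat.X.nnz == 9
        assert mat.X[0, 0] == 0

    def test_zero_fraction_is_pure_binarization_and_idempotent(self, rng):
        dense = rng.integers(0, 5, size=(20, 30))
        mat = binarize(counts_from_dense(dense), top_fraction=0.0)
        assert set(mat.X.data.tolist()) <= {1}
        again = binarize(counts_from_dense(mat.X.toarray()), top_fraction=0.0)
        assert (again.X != mat.X).nnz == 0

    def test_coverage_recomputed_from_binary(self, rng):
        dense = rng.integers(0, 3, size=(5, 40))
        mat = binarize(counts_from_dense(dense), top_fraction=0.0)
        np.testing.assert_array_equal(mat.coverage, (dense > 0).sum(axis=1))
        np.testing.assert_allclose(mat.p, mat.coverage / 40)

    def test_all_zero_matrix_unchanged(self):
        mat = binarize(counts_from_dense(np.zeros((3, 10), dtype=int)))
        assert mat.X.nnz == 0


class TestFilterBins:
    def toy(self, n=20, m=100, cov_scale=1):
        rng = np.random.default_rng(3)
        dense = (rng.random((n, m)) < 0.4).astype(int)
        dense[:, 0] = 1  # guarantee the blacklisted bin is non-empty
        mat = binarize(counts_from_dense(dense, bin_size=100), top_fraction=0)
        return mat

    def test_blacklist_single_bp_overlap_removes_bin(self):
        mat = self.toy()
        # bin 0 is chr1:[0,100); blacklist [99,200) overlaps it by 1 bp
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [200]})
        out = filter_bins(mat, blacklist=bl, top_coverage_fraction=0)
        assert out.n_bins == mat.n_bins - 2  # bins 0 and 1 both overlap
        assert not out.kept_bins[0] and not out.kept_bins[1]

    def test_low_coverage_skips_top_filter(self):
        mat = self.toy()  # mean coverage way below 5000
        out = filter_bins(mat, top_coverage_fraction=0.05)
        assert out.n_bins == mat.n_bins

    def test_top_fraction_removed_with_floor(self):
        mat = self.toy()
        out = filter_bins(mat, top_coverage_fraction=0.05, low_coverage_skip=0)
        assert out.n_bins == mat.n_bins - int(np.floor(0.05 * mat.n_bins))
        # removed bins are the highest-coverage ones
        colsum = np.asarray(mat.X.sum(axis=0)).ravel()
        removed = ~out.kept_bins
        assert colsum[removed].min() >= np.sort(colsum)[::-1][removed.sum() - 1]

    def test_excluded_chromosome_bins_removed(self):
        mat = self.toy()
        bins = mat.bin_coords.copy()
        bins.loc[:9, "chrom"] = "chrX"
        mat = CellByBinMatrix(X=mat.X, cell_barcodes=mat.cell_barcodes,
                              bin_coords=bins)
        out = filter_bins(mat, top_coverage_fraction=0)
        assert out.n_bins == mat.n_bins - 10

    def test_surviving_entries_unchanged(self):
        mat = self.toy()
        out = filter_bins(mat, top_coverage_fraction=0.05, low_coverage_skip=0)
        kept = out.kept_bins
        np.testing.assert_array_equal(out.X.toarray(),
                                      mat.X.toarray()[:, kept])

    def test_all_bins_removed_raises(self):
        mat = self.toy()
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        with pytest.raises(ValueError, match="no features remain"):
            filter_bins(mat, blacklist=bl)
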