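"""Expression ingestion and normalization behaviour."""

import numpy as np
import pandas as pd
import pytest

from tnbcstrat.matrix import (
    ExpressionMatrix,
    collapse_probes,
    counts_to_logcpm,
    intersect_genes,
    mad_scale,
    median_center,
    read_expression,
    write_expression,
)

from conftest import make_matrix


TSV_CONTENT = "gene\tS1\tS2\nTP53\t1.0\t2.0\nGZMA\t3.0\t4.0\nPRF1\t5.0\t6.0\n"


class TestReadExpression:
    def test_tsv_roundtrip_identity(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(TSV_CONTENT)
        m = read_expression(path, "tsv")
        assert m.shape == (3, 2)
        assert list(m.gene_ids) == ["TP53", "GZMA", "PRF1"]
        assert m.values.loc["GZMA", "S2"] == 4.0
        assert m.provenance == frozenset()

    def test_gct_equals_tsv_twin(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(TSV_CONTENT)
        gct = tmp_path / "m.gct"
        gct.write_text(
            "#1.2\n3\t2\nName\tDescription\tS1\tS2\n"
            "TP53\tna\t1.0\t2.0\nGZMA\tna\t3.0\t4.0\nPRF1\tna\t5.0\t6.0\n"
        )
        a = read_expression(tsv, "tsv")
        b = read_expression(gct, "gct")
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_row_with_missing_value_dropped(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tS1\tS2\nA\t1\t2\nB\tNA\t3\nC\t4\t5\n")
        m = read_expression(path)
        assert list(m.gene_ids) == ["A", "C"]

    def test_malformed_gct_header_rejected(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.3\n1\t1\nName\tDescription\tS1\nA\tna\t1\n")
        with pytest.raises(ValueError, match="GCT"):
            read_expression(path, "gct")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\tS1\tS1\nA\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_expression(path)

    def test_writer_reader_roundtrip(self, tmp_path):
        m = make_matrix([[1.5, 2.5], [3.5, 4.5]], genes=["A", "B"])
        for fmt in ("tsv", "gct"):
            path = tmp_path / f"out.{fmt}"
            write_expression(m, path, fmt)
            back = read_expression(path, fmt)
            pd.testing.assert_frame_equal(back.values, m.values, check_names=False)


class TestCollapseProbes:
    def test_highest_iqr_probe_kept(self):
        m = make_matrix([[1, 1, 1, 1], [0, 2, 4, 6]], genes=["P1", "P2"])
        out = collapse_probes(m, {"P1": "GENE1", "P2": "GENE1"})
        assert out.shape == (1, 4)
        assert list(out.values.loc["GENE1"]) == [0, 2, 4, 6]
        assert "collapsed" in out.provenance

    def test_single_probe_gene_unchanged(self):
        m = make_matrix([[1, 2, 3]], genes=["P1"])
        out = collapse_probes(m, {"P1": "GENE1"})
        assert list(out.values.loc["GENE1"]) == [1, 2, 3]

    def test_iqr_tie_broken_by_file_order(self):
        # both probes have identical IQR; brute-force scan oracle keeps the
        # first probe encountered in file order
        rows = [[0, 1, 2, 3], [10, 11, 12, 13], [5, 6, 7, 8]]
        m = make_matrix(rows, genes=["PA", "PB", "PC"])
        probe_map = {"PA": "GENE1", "PB": "GENE1", "PC": "GENE1"}
        iqr = [np.percentile(r, 75) - np.percentile(r, 25) for r in rows]
        best, best_iqr = "PA", iqr[0]   # oracle: linear scan, strict improvement
        for probe, value in zip(["PB", "PC"], iqr[1:]):
            if value > best_iqr:
                best, best_iqr = probe, value
        out = collapse_probes(m, probe_map)
        expected_row = rows[["PA", "PB", "PC"].index(best)]
        assert list(out.values.loc["GENE1"]) == expected_row

    def test_unmapped_probes_dropped(self):
        m = make_matrix([[1, 2], [3, 4]], genes=["P1", "PX"])
        out = collapse_probes(m, {"P1": "GENE1"})
        assert list(out.gene_ids) == ["GENE1"]

    def test_gene_count_equals_distinct_symbols(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(10, 4)), genes=[f"P{i}" for i in range(10)])
        probe_map = {f"P{i}": f"GENE{i % 4}" for i in range(10)}
        out = collapse_probes(m, probe_map)
        assert out.shape[0] == 4


class TestMadScale:
    def test_formula_on_simple_column(self):
        # (1,2,3): median 2, MAD 1 -> (x-2)/1.4826
        m = make_matrix([[1], [2], [3]])
        out = mad_scale(m)
        expected = np.array([-1, 0, 1]) / 1.4826
        np.testing.assert_allclose(out.values.iloc[:, 0], expected, atol=1e-12)
        assert "mad_scaled" in out.provenance

    def test_constant_sample_rejected(self):
        m = make_matrix([[1, 1], [1, 2], [1, 3]], samples=["BAD", "OK"])
        with pytest.raises(ValueError, match="BAD"):
            mad_scale(m)

    def test_scaled_output_has_median_zero_and_unit_scale(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(2.0, 3.0, size=(51, 5)))
        out = mad_scale(m).values
        np.testing.assert_allclose(out.median(axis=0), 0.0, atol=1e-12)
        mad = (out - out.median(axis=0)).abs().median(axis=0) * 1.4826
        np.testing.assert_allclose(mad, 1.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(31, 4)))
        once = mad_scale(m)
        twice = mad_scale(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)


class TestIntersectGenes:
    def test_restricted_to_common_sorted_genes(self):
        a = make_matrix([[1, 2], [3, 4], [5, 6]], genes=["A", "B", "C"])
        b = make_matrix([[1, 2], [3, 4], [5, 6]], genes=["B", "C", "D"])
        out_a, out_b = intersect_genes([a, b])
        assert list(out_a.gene_ids) == list(out_b.gene_ids) == ["B", "C"]

    def test_identical_matrices_unchanged(self):
        a = make_matrix([[1, 2], [3, 4]], genes=["A", "B"])
        out_a, out_b = intersect_genes([a, a])
        pd.testing.assert_frame_equal(out_a.values, a.values)

    def test_empty_triple_intersection_rejected(self):
        a = make_matrix([[1]], genes=["A"])
        b = make_matrix([[1]], genes=["B"])
        c = make_matrix([[1]], genes=["C"])
        with pytest.raises(ValueError, match="empty"):
            intersect_genes([a, b, c])

    def test_order_insensitive_membership(self):
        a = make_matrix([[1, 2], [3, 4], [5, 6]], genes=["A", "B", "C"])
        b = make_matrix([[9, 8], [7, 6]], genes=["C", "B"])
        ab = intersect_genes([a, b])
        ba = intersect_genes([b, a])
        assert list(ab[0].gene_ids) == list(ba[0].gene_ids)


class TestMedianCenter:
    def test_row_median_removed(self):
        m = make_matrix([[1, 2, 3]])
        out = median_center(m)
        assert list(out.values.iloc[0]) == [-1, 0, 1]
        assert "median_centered" in out.provenance

    def test_idempotent_and_zero_median(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(7, 9)))
        once = median_center(m)
        np.testing.assert_allclose(once.values.median(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(median_center(once).values, once.values, atol=1e-12)


class TestCountsToLogcpm:
    def test_direct_evaluation(self):
        # 2-gene sample: counts (999999, 1); library 1e6, prior 0.5
        m = make_matrix([[999999], [1]])
        out = counts_to_logcpm(m, prior=0.5)
        expected = np.log2((999999 + 0.5) / (1e6 + 1.0) * 1e6)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert out.values.iloc[0, 0] == pytest.approx(19.93, abs=0.01)

    def test_all_zero_counts_symmetric_across_samples(self):
        m = make_matrix(np.zeros((4, 3)))
        out = counts_to_logcpm(m, prior=0.5).values
        assert out.nunique(axis=1).max() == 1

    def test_depth_invariance_at_moderate_counts(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(100, 1000, size=(50, 1)).astype(float)
        a = counts_to_logcpm(make_matrix(counts)).values
        b = counts_to_logcpm(make_matrix(2 * counts)).values
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            counts_to_logcpm(make_matrix([[-1, 2]]))
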