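"""Panel readers, identifier normalization and harmonization."""

import gzip
import logging

import numpy as np
import pandas as pd
import pytest

from drugcorr.panel_io import (
    ExpressionMatrix,
    LineageAnnotation,
    PanelFormatError,
    PanelValidationError,
    ResponseTable,
    harmonize,
    normalize_cell_line_id,
    read_annotation_tsv,
    read_expression_gct,
    read_expression_tsv,
    read_response_tsv,
    write_annotation_tsv,
    write_expression_tsv,
    write_response_tsv,
)


class TestNormalizeCellLineId:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("SK-MEL-28", "SKMEL28"),
            ("skmel28", "SKMEL28"),
            ("NCI-H460 (lung)", "NCIH460LUNG"),
            ("786-O", "786O"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_cell_line_id(raw) == expected

    def test_idempotent_and_case_insensitive(self):
        for raw in ["SK-MEL-28", "hep g2", "T.T", "U-87 MG"]:
            once = normalize_cell_line_id(raw)
            assert normalize_cell_line_id(once) == once
            assert normalize_cell_line_id(raw.lower()) == once

    @pytest.mark.parametrize("raw", ["", "   ", "---"])
    def test_rejects_empty(self, raw):
        with pytest.raises(PanelValidationError):
            normalize_cell_line_id(raw)


EXPR_TSV = (
    "gene\tSK-MEL-28\tA-375\tNCI-H460\tHep G2\n"
    "NQO1\t1.0\t2.0\t3.0\t4.0\n"
    "VEGFA\t4.0\tNA\t2.0\t1.0\n"
    "MET\t0.5\t0.5\t0.5\t0.5\n"
)


class TestExpressionReaders:
    def test_tsv_reader_shape_and_normalized_columns(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text(EXPR_TSV)
        mat = read_expression_tsv(path)
        assert mat.data.shape == (3, 4)
        assert mat.cell_line_ids == ["SKMEL28", "A375", "NCIH460", "HEPG2"]
        assert mat.gene_ids == ["NQO1", "VEGFA", "MET"]
        assert np.isnan(mat.data.loc["VEGFA", "A375"])

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "expr.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(EXPR_TSV)
        assert read_expression_tsv(path).data.shape == (3, 4)

    def test_duplicate_gene_rows_keep_first_with_warning(self, tmp_path, caplog):
        path = tmp_path / "expr.tsv"
        path.write_text(
            "gene\tA1\tB2\tC3\nNQO1\t1\t2\t3\nNQO1\t9\t9\t9\nMET\t4\t5\t6\n"
        )
        with caplog.at_level(logging.WARNING):
            mat = read_expression_tsv(path)
        assert mat.data.loc["NQO1"].tolist() == [1.0, 2.0, 3.0]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_duplicate_cell_line_columns_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene\tSK-MEL-28\tSKMEL28\tA375\nNQO1\t1\t2\t3\n")
        with pytest.raises(PanelValidationError):
            read_expression_tsv(path)

    def test_gct_roundtrip_of_values(self, tmp_path):
        path = tmp_path / "expr.gct"
        path.write_text(
            "#1.2\n3\t4\n"
            "Name\tDescription\tSK-MEL-28\tA-375\tNCI-H460\tHep G2\n"
            "NQO1\tna\t1.0\t2.0\t3.0\t4.0\n"
            "VEGFA\tna\t4.0\t3.0\t2.0\t1.0\n"
            "MET\tna\t0.5\t0.5\t0.5\t0.5\n"
        )
        mat = read_expression_gct(path)
        assert mat.data.shape == (3, 4)
        assert mat.data.loc["NQO1", "HEPG2"] == 4.0

    def test_gct_dimension_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text(
            "#1.2\n3\t4\n"
            "Name\tDescription\tA1\tB2\tC3\tD4\tE5\n"
            "NQO1\tna\t1\t2\t3\t4\t5\n"
            "VEGFA\tna\t1\t2\t3\t4\t5\n"
            "MET\tna\t1\t2\t3\t4\t5\n"
        )
        with pytest.raises(PanelFormatError):
            read_expression_gct(path)

    def test_gct_requires_version_line(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.3\n1\t3\nName\tDescription\tA\tB\tC\nG\tna\t1\t2\t3\n")
        with pytest.raises(PanelFormatError):
            read_expression_gct(path)


RESP_TSV = (
    "cell_line\tdrug\tmetric\tvalue\tunits\n"
    "SK-MEL-28\t17-AAG\tEC50\t0.1\tuM\n"
    "A-375\t17-AAG\tEC50\tNA\tuM\n"
    "NCI-H460\t17-AAG\tEC50\t2.0\tuM\n"
    "Hep G2\t17-AAG\tEC50\t1.0\tuM\n"
    "Hep G2\tPLX4720\tIC50\t1.0\tuM\n"
    "HEPG2\tPLX4720\tIC50\t3.0\tuM\n"
)


class TestResponseReader:
    def test_missing_values_dropped_and_replicates_averaged(self, tmp_path):
        path = tmp_path / "resp.tsv"
        path.write_text(RESP_TSV)
        table = read_response_tsv(path)
        # 6 rows -> 1 dropped (NA) -> replicate pair averaged -> 4 records
        assert len(table.data) == 4
        plx = table.data.query("drug == 'PLX4720'")
        assert plx["value"].tolist() == [2.0]
        assert plx["cell_line"].tolist() == ["HEPG2"]

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "resp.tsv"
        path.write_text("cell_line\tmetric\tvalue\nA1\tIC50\t1.0\n")
        with pytest.raises(PanelFormatError):
            read_response_tsv(path)

    def test_configurable_column_names(self, tmp_path):
        path = tmp_path / "resp.tsv"
        path.write_text("CCLE line\tCompound\tkind\tconc\nSK-MEL-28\tD\tic50\t1.5\n")
        table = read_response_tsv(
            path, cell_line_col="CCLE line", drug_col="Compound",
            metric_col="kind", value_col="conc",
        )
        assert table.data.iloc[0].tolist() == ["SKMEL28", "D", "IC50", 1.5, ""]


class TestAnnotationReader:
    def test_basic_mapping(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("cell_line\tlineage\nSK-MEL-28\tmelanoma\nNCI-H460\tNSCLC\n")
        ann = read_annotation_tsv(path)
        assert ann.lineage_of == {"SKMEL28": "melanoma", "NCIH460": "NSCLC"}

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("cell_line\tlineage\nSK-MEL-28\tmelanoma\nskmel28\tlung\n")
        with pytest.raises(PanelValidationError):
            read_annotation_tsv(path)


def _components(lines, genes=("G1",)):
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.arange(len(genes) * len(lines), dtype=float).reshape(len(genes), -1),
            index=list(genes),
            columns=list(lines),
        )
    )
    resp = ResponseTable(
        pd.DataFrame(
            [(c, "D", "IC50", 1.0 + i) for i, c in enumerate(lines)],
            columns=["cell_line", "drug", "metric", "value"],
        )
    )
    ann = LineageAnnotation({c: "lung" for c in lines})
    return expr, resp, ann


class TestHarmonize:
    def test_restricts_to_intersection(self):
        expr, _, _ = _components(["A1", "B2", "C3"])
        _, resp, _ = _components(["B2", "C3", "D4"])
        _, _, ann = _components(["A1", "B2", "C3", "D4"])
        panel = harmonize(expr, resp, ann)
        assert panel.cell_lines == ["B2", "C3"]
        assert panel.response.cell_line_ids == {"B2", "C3"}

    def test_disjoint_sets_rejected(self):
        expr, _, _ = _components(["A1", "B2", "C3"])
        _, resp, ann = _components(["X1", "Y2", "Z3"])
        with pytest.raises(PanelValidationError):
            harmonize(expr, resp, ann)

    def test_idempotent(self):
        expr, resp, ann = _components(["A1", "B2", "C3", "D4"])
        once = harmonize(expr, resp, ann)
        twice = harmonize(once.expression, once.response, once.annotation)
        pd.testing.assert_frame_equal(once.expression.data, twice.expression.data)
        pd.testing.assert_frame_equal(once.response.data, twice.response.data)
        assert once.annotation.lineage_of == twice.annotation.lineage_of

    def test_roundtrip_through_writers(self, tmp_path):
        expr, resp, ann = _components(["A1", "B2", "C3", "D4"], genes=("G1", "G2"))
        panel = harmonize(expr, resp, ann)
        write_expression_tsv(panel.expression, tmp_path / "e.tsv")
        write_response_tsv(panel.response, tmp_path / "r.tsv")
        write_annotation_tsv(panel.annotation, tmp_path / "a.tsv")
        re_expr = read_expression_tsv(tmp_path / "e.tsv")
        re_resp = read_response_tsv(tmp_path / "r.tsv")
        re_ann = read_annotation_tsv(tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(
            panel.expression.data, re_expr.data, check_names=False
        )
        pd.testing.assert_frame_equal(panel.response.data, re_resp.data)
        assert panel.annotation.lineage_of == re_ann.lineage_of
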