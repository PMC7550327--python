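"""Plate geometry, layout construction and table I/O."""

import numpy as np
import pandas as pd
import pytest

from glycoscreen import build_layout, read_screen_table, write_screen_table
from glycoscreen.plate_model import (ExpressionProfile, LIBRARY_COLUMNS,
                                     LIBRARY_WELLS_PER_PLATE, ScreenTableError,
                                     WellRole, format_well, parse_well,
                                     write_results_table, read_results_table,
                                     RESULTS_COLUMNS)
from glycoscreen.synthetic_screen import make_gene_table


def role_counts(layout, plate=1):
    return layout[layout["plate"] == plate]["role"].value_counts().to_dict()


class TestWellAddress:
    @pytest.mark.parametrize("well,expected", [
        ("A01", ("A", 1)), ("P24", ("P", 24)), ("h3", ("H", 3))])
    def test_parse(self, well, expected):
        assert parse_well(well) == expected

    @pytest.mark.parametrize("bad", ["Q01", "A0", "A25", "11", "AA1", ""])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            parse_well(bad)

    def test_format_roundtrip(self):
        for r in "AP":
            for c in (1, 9, 24):
                assert parse_well(format_well(r, c)) == (r, c)


class TestBuildLayout:
    @pytest.mark.parametrize("n_plates", [1, 2, 3])
    def test_control_counts_per_plate(self, n_plates):
        genes = make_gene_table(n_plates * 100)
        layout = build_layout(n_plates, genes=genes)
        for p in range(1, n_plates + 1):
            counts = role_counts(layout, p)
            assert counts[WellRole.NT.value] == 16
            assert counts[WellRole.PLK1.value] == 8
            assert counts[WellRole.PDK1.value] == 8
            assert counts[WellRole.MEDIA.value] == 16

    def test_empty_library_plate(self):
        layout = build_layout(1)
        counts = role_counts(layout)
        assert WellRole.LIBRARY.value not in counts
        assert counts[WellRole.EMPTY.value] == LIBRARY_WELLS_PER_PLATE
        assert len(layout) == 384

    def test_genome_scale_capacity(self):
        # 18,120 pools fit on 58 plates with the last plate partially filled
        genes = make_gene_table(18120)
        layout = build_layout(58, genes=genes)
        placed = layout[layout["role"] == WellRole.LIBRARY.value]
        assert len(placed) == 18120
        last = layout[layout["plate"] == 58]
        assert (last["role"] == WellRole.EMPTY.value).sum() > 0
        assert 58 * LIBRARY_WELLS_PER_PLATE >= 18120

    def test_row_major_fill(self):
        layout = build_layout(1, genes=make_gene_table(30))
        placed = layout[layout["role"] == WellRole.LIBRARY.value]
        first = placed.iloc[0]
        assert (first["row"], first["col"]) == ("A", LIBRARY_COLUMNS[0])
        # fill proceeds along row A before any row-B well
        assert (placed.iloc[:21]["row"] == "A").all()

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="exceed"):
            build_layout(1, genes=make_gene_table(337))

    def test_deconvolution_requires_four_duplexes(self):
        genes = make_gene_table(2)
        genes["duplex"] = [1, 2]
        with pytest.raises(ValueError, match="4 distinct duplexes"):
            build_layout(1, genes=genes, deconvolution=True)


class TestScreenTableIO:
    def test_roundtrip_identity(self, small_noisy_screen, tmp_path):
        path = tmp_path / "screen.csv"
        df = small_noisy_screen.measurements
        write_screen_table(df, path, header_comment="roundtrip test")
        back = read_screen_table(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), df.reset_index(drop=True),
            check_dtype=False)

    def test_t0_with_absorbance_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "library_plate,arm,replicate,well,row,col,role,catalog_id,"
            "entrez_id,duplex,cell_count,absorbance\n"
            "1,control,1,A01,A,1,library,M-1,101,0,900,0.5\n"
            "1,T0,1,A01,A,1,library,M-1,101,0,900,0.5\n")
        with pytest.raises(ScreenTableError, match="T0") as err:
            read_screen_table(path)
        assert err.value.lines == [3]

    @pytest.mark.parametrize("row,reason", [
        ("1,mock,1,A01,A,1,library,M-1,101,0,900,0.5", "unknown arm"),
        ("1,control,1,A01,A,1,library,M-1,101,0,-4,0.5", "negative"),
        ("1,control,1,Z99,Z,99,library,M-1,101,0,4,0.5", "well"),
    ])
    def test_malformed_rows(self, tmp_path, row, reason):
        path = tmp_path / "bad.csv"
        path.write_text(
            "library_plate,arm,replicate,well,row,col,role,catalog_id,"
            "entrez_id,duplex,cell_count,absorbance\n" + row + "\n")
        with pytest.raises(ScreenTableError, match=reason):
            read_screen_table(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        line = "1,control,1,A01,A,1,library,M-1,101,0,900,0.5\n"
        path.write_text(
            "library_plate,arm,replicate,well,row,col,role,catalog_id,"
            "entrez_id,duplex,cell_count,absorbance\n" + line + line)
        with pytest.raises(ScreenTableError, match="duplicate"):
            read_screen_table(path)


class TestResultsTable:
    def test_fixed_columns_and_missing_sentinel(self, tmp_path):
        metrics = pd.DataFrame({
            "catalog_id": [f"M-{i}" for i in range(10)],
            "entrez_id": range(10),
            "lactate_fc_control": [0.5] * 9 + [np.nan],
            "exclusion_reason": [""] * 9 + ["low_cell_density"],
        })
        path = tmp_path / "results.csv"
        write_results_table(metrics, path)
        text = path.read_text().splitlines()
        assert text[0].split(",") == RESULTS_COLUMNS
        assert len(text) == 11
        # excluded gene: lactate field empty, reason recorded
        last = dict(zip(RESULTS_COLUMNS, text[-1].split(",")))
        assert last["lactate_fc_control"] == ""
        assert last["exclusion_reason"] == "low_cell_density"

    def test_roundtrip(self, tmp_path):
        metrics = pd.DataFrame({
            "catalog_id": ["M-1", "M-2"], "entrez_id": [1, 2],
            "t48_fc_control": [1.0, 0.25]})
        path = tmp_path / "results.csv"
        write_results_table(metrics, path, header_comment="prov")
        back = read_results_table(path)
        assert list(back["catalog_id"]) == ["M-1", "M-2"]
        assert np.allclose(back["t48_fc_control"], [1.0, 0.25])


class TestExpressionProfile:
    def test_percentile_and_lookup(self):
        prof = ExpressionProfile(pd.Series(np.arange(1.0, 101.0),
                                           index=np.arange(1, 101)))
        assert prof.percentile(0) == 1.0
        assert prof.value(5) == 5.0
        assert np.isnan(prof.value(999))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ExpressionProfile(pd.Series(dtype=float))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionProfile(pd.Series([1.0, 2.0], index=[7, 7]))
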