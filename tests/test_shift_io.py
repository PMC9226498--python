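"""I/O round-trips and validation for the TSV dialect, NMR-STAR subset,
aligned FASTA, and PDB painting."""

import io

import pytest

from fingermap import (
    AmidePeak,
    DataError,
    ShiftRecord,
    ShiftTable,
    TitrationPoint,
    TitrationSeries,
    paint_structure,
    read_alignment,
    read_peak_list,
    read_shift_table,
    read_titration,
    write_peak_list,
    write_shift_table,
    write_titration,
)

SHIFT_TSV = "residue\taa\tatom\tshift_ppm\n1\tM\tH\t8.30\n2\tA\tH\t8.10\n3\tG\tH\t8.45\n"


class TestShiftTable:
    def test_parses_three_rows(self):
        table = read_shift_table(io.StringIO(SHIFT_TSV))
        assert len(table) == 3
        assert table.get(2, "H") == 8.10
        assert table.report.n_parsed == 3

    def test_empty_stream_errors(self):
        with pytest.raises(DataError, match="no records"):
            read_shift_table(io.StringIO(""))

    def test_unsupported_atom_skipped_and_counted(self):
        text = SHIFT_TSV + "4\tL\tHB\t1.20\n"
        table = read_shift_table(io.StringIO(text))
        assert len(table) == 3
        assert table.report.n_skipped == 1
        assert "HB" in table.report.skipped[0]

    def test_malformed_row_names_line(self):
        text = "residue\taa\tatom\tshift_ppm\n1\tM\tH\tnot_a_number\n"
        with pytest.raises(DataError, match="line 2"):
            read_shift_table(io.StringIO(text))

    def test_duplicate_residue_atom_errors(self):
        with pytest.raises(DataError, match="duplicate"):
            ShiftTable([ShiftRecord(1, "A", "H", 8.0), ShiftRecord(1, "A", "H", 8.1)])

    def test_write_read_identity(self):
        table = read_shift_table(io.StringIO(SHIFT_TSV))
        buf = io.StringIO()
        write_shift_table(table, buf)
        again = read_shift_table(io.StringIO(buf.getvalue()))
        assert [(r.residue_number, r.residue_type, r.atom, r.shift) for r in again.records] == [
            (r.residue_number, r.residue_type, r.atom, r.shift) for r in table.records
        ]

    def test_nmrstar_subset(self):
        star = """
data_test
loop_
  _Atom_chem_shift.ID
  _Atom_chem_shift.Comp_index_ID
  _Atom_chem_shift.Comp_ID
  _Atom_chem_shift.Atom_ID
  _Atom_chem_shift.Val
  1 1 MET H 8.30
  2 1 MET N 120.1
  3 1 MET HB 2.10
  4 2 ALA CA 52.5
stop_
"""
        table = read_shift_table(io.StringIO(star), dialect="nmrstar_subset")
        assert len(table) == 3
        assert table.get(1, "N") == 120.1
        assert table.get(2, "CA") == 52.5
        assert table.report.n_skipped == 1


class TestTitrationIO:
    def _series(self):
        peaks0 = [AmidePeak(1, 8.0, 120.0), AmidePeak(2, 8.5, 115.0)]
        peaks1 = [AmidePeak(1, 8.1, 120.5), AmidePeak(2, 8.5, 115.0)]
        return TitrationSeries(
            [
                TitrationPoint(1e-4, 0.0, peaks0),
                TitrationPoint(1e-4, 2e-4, peaks1),
            ]
        )

    def test_manifest_round_trip(self, tmp_path):
        series = self._series()
        manifest = write_titration(series, str(tmp_path))
        again = read_titration(manifest)
        assert len(again) == 2
        assert again.apo.l_total == 0.0
        assert again.points[1].peak_map()[1].h_ppm == pytest.approx(8.1)

    def test_missing_apo_errors(self):
        peaks = [AmidePeak(1, 8.0, 120.0)]
        with pytest.raises(DataError, match="apo"):
            TitrationSeries(
                [TitrationPoint(1e-4, 1e-4, peaks), TitrationPoint(1e-4, 2e-4, peaks)]
            )

    def test_new_residue_after_apo_errors(self):
        with pytest.raises(DataError, match="residue 3"):
            TitrationSeries(
                [
                    TitrationPoint(1e-4, 0.0, [AmidePeak(1, 8.0, 120.0)]),
                    TitrationPoint(1e-4, 1e-4, [AmidePeak(3, 8.0, 120.0)]),
                ]
            )

    def test_unsorted_points_sorted_on_read(self, tmp_path):
        series = self._series()
        write_titration(series, str(tmp_path))
        # shuffle manifest rows
        manifest = tmp_path / "manifest.tsv"
        lines = manifest.read_text().splitlines()
        manifest.write_text("\n".join([lines[0], lines[2], lines[1]]) + "\n")
        again = read_titration(str(manifest))
        ratios = [pt.ratio for pt in again.points]
        assert ratios == sorted(ratios)

    def test_prolines_never_in_peaks(self):
        # absence is representational: a residue simply has no row
        peaks = read_peak_list(io.StringIO("residue\th_ppm\tn_ppm\n2\t8.1\t119.0\n"))
        assert [p.residue_number for p in peaks] == [2]


class TestAlignmentIO:
    def test_reads_and_uppercases(self):
        fasta = ">a\nacdefghiklmnpqrstvwy-ac\n>b\nACDEFGHIKLMNPQRSTVWYXAC\n"
        aln = read_alignment(io.StringIO(fasta))
        assert aln.width == 23
        assert len(aln) == 2
        assert aln.seqs[0].isupper()

    def test_ragged_errors(self):
        with pytest.raises(DataError):
            read_alignment(io.StringIO(">a\nACDE\n>b\nACD\n"))

    def test_invalid_symbol_errors(self):
        with pytest.raises(DataError, match="invalid symbol"):
            read_alignment(io.StringIO(">a\nAC*E\n"))


PDB_MINI = (
    "HEADER    TEST\n"
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N\n"
    "ATOM      2  CA  ALA A   1      11.804   7.381  -6.204  1.00 10.00           C\n"
    "ATOM      3  N   GLY A   2      12.104   8.134  -7.504  1.00 10.00           N\n"
    "END\n"
)


class TestPaintStructure:
    def test_score_written_per_residue(self):
        out = paint_structure(PDB_MINI, {1: 0.5}, default=0.0)
        lines = out.splitlines()
        assert lines[1][60:66] == "  0.50"
        assert lines[2][60:66] == "  0.50"
        assert lines[3][60:66] == "  0.00"

    def test_clipping(self):
        out = paint_structure(PDB_MINI, {1: 1e6, 2: -5.0})
        lines = out.splitlines()
        assert lines[1][60:66] == "999.99"
        assert lines[3][60:66] == "  0.00"

    def test_only_bfactor_column_changes(self):
        out = paint_structure(PDB_MINI, {}, default=7.25)
        for before, after in zip(PDB_MINI.splitlines(), out.splitlines()):
            if before.startswith("ATOM"):
                assert after[:60] == before[:60]
                assert after[66:] == before[66:]
                assert after[60:66] == "  7.25"
            else:
                assert after == before

    def test_unreadable_pdb_errors(self):
        with pytest.raises(DataError, match="unreadable"):
            paint_structure("HEADER only\nEND\n", {1: 0.5})
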