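"""File formats: peak lists, vd lists, sequences, CSV and PyMOL output."""

import warnings

import numpy as np
import pytest

from relaxdisp import (
    FieldContext,
    ModelParams,
    SimulationSpec,
    fit_residue,
    select_model,
    simulate_profile,
)
from relaxdisp.fileio import (
    ProjectConfig,
    read_peak_list,
    read_sequence,
    read_vd_list,
    schedule_from_vd,
    write_profiles_csv,
    write_pymol_macro,
    write_results_csv,
)


class TestReadPeakList:
    def test_generic_tsv(self, tmp_path):
        p = tmp_path / "s0.tsv"
        p.write_text("# residue intensity\n24\t1.00e6\n30\t8.5e5\n")
        col = read_peak_list(p, "generic_tsv")
        assert col[24] == 1.0e6 and col[30] == 8.5e5
        assert col.name == "s0"

    def test_sparky_like_assignments(self, tmp_path):
        p = tmp_path / "sp.list"
        p.write_text(
            "Assignment w1 w2 Height\n"
            "W24N-H 129.1 10.1 1.2e6\n"
            "F30N-H 120.3 8.9 9.0e5\n"
        )
        col = read_peak_list(p, "sparky_like")
        assert col[24] == 1.2e6 and col[30] == 9.0e5

    def test_nmrview_table(self, tmp_path):
        p = tmp_path / "nv.tbl"
        p.write_text(
            "Label Residue Shift Intensity\n"
            "W 24 129.1 1.10e6\n"
            "F 30 120.3 8.00e5\n"
        )
        col = read_peak_list(p, "nmrview_table")
        assert col[24] == 1.1e6 and col[30] == 8.0e5

    def test_bad_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("24\t1e6\nnot-a-row\t??\n")
        with pytest.warns(UserWarning, match=":2"):
            col = read_peak_list(p)
        assert list(col.index) == [24]

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# nothing\n")
        with pytest.raises(ValueError):
            read_peak_list(p)


class TestReadVdList:
    def test_frequency_mode_with_replicates(self, tmp_path):
        p = tmp_path / "vd"
        p.write_text("0\n25\n50\n50\n2000\n")
        vals = read_vd_list(p, t_cpmg=0.08, mode="frequency_hz")
        assert vals == [None, 25.0, 50.0, 50.0, 2000.0]

    def test_loop_count_mode(self, tmp_path):
        p = tmp_path / "vc"
        p.write_text("0\n2\n4\n")
        assert read_vd_list(p, t_cpmg=0.08, mode="loop_count") == [None, 25.0, 50.0]

    def test_negative_entry_is_error(self, tmp_path):
        p = tmp_path / "vd"
        p.write_text("0\n-5\n")
        with pytest.raises(ValueError):
            read_vd_list(p, t_cpmg=0.08)

    def test_schedule_construction(self, tmp_path):
        p = tmp_path / "vd"
        p.write_text("0\n25\n50\n")
        sched = schedule_from_vd(p, 0.08, FieldContext(600.0))
        assert sched.reference_ids == ["spec_0"]
        assert [pt.nu_cpmg for pt in sched.cpmg_points] == [25.0, 50.0]


_PDB_LINE = (
    "ATOM  {serial:>5d}  CA  {resname} A{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def _write_pdb(path, residues):
    with open(path, "w") as fh:
        fh.write("HEADER    SYNTHETIC TEST STRUCTURE\n")
        for i, (num, name) in enumerate(residues, 1):
            fh.write(
                _PDB_LINE.format(
                    serial=i, resname=name, resseq=num, x=float(i), y=0.0, z=0.0
                )
            )
        fh.write("END\n")


class TestReadSequence:
    def test_fasta(self, tmp_path):
        p = tmp_path / "seq.fasta"
        p.write_text(">toxin\nMKWCFG\nLAVN\n")
        seq = read_sequence(p)
        assert len(seq) == 10
        assert seq[1] == "M" and seq[3] == "W" and seq[10] == "N"

    def test_plain_string(self):
        seq = read_sequence("ACDEFG")
        assert seq == {1: "A", 2: "C", 3: "D", 4: "E", 5: "F", 6: "G"}

    def test_pdb_atom_records_keep_author_numbering(self, tmp_path):
        p = tmp_path / "model.pdb"
        _write_pdb(p, [(24, "TRP"), (30, "PHE")])
        seq = read_sequence(p)
        assert seq == {24: "W", 30: "F"}

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            read_sequence("")


class TestWriters:
    def _fits(self, seed=0):
        params = ModelParams(2, r20=15.23, kex=3750.3, phi=47457.4)
        prof = simulate_profile(
            SimulationSpec(params=params, seed=seed, noise_percent=5)
        )
        fits = [fit_residue(prof, m) for m in (1, 2, 3)]
        select_model(fits)
        return prof, fits

    def test_results_csv_layout_and_round_trip(self, tmp_path):
        import pandas as pd

        _, fits = self._fits()
        out = tmp_path / "results.csv"
        write_results_csv(fits, out)
        frame = pd.read_csv(out)
        assert len(frame) == 3
        assert frame["selected"].sum() == 1
        assert list(frame.columns[:3]) == ["residue", "model", "selected"]
        row2 = frame[frame["model"] == 2].iloc[0]
        assert row2["kex"] == pytest.approx(fits[1].params.kex, rel=1e-5)
        assert row2["rex"] == pytest.approx(
            fits[1].params.phi / fits[1].params.kex, rel=1e-5
        )

    def test_writers_are_deterministic(self, tmp_path):
        prof, fits = self._fits()
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_results_csv(fits, a)
        write_results_csv(fits, b)
        assert a.read_bytes() == b.read_bytes()
        pa, pb_ = tmp_path / "pa.csv", tmp_path / "pb.csv"
        write_profiles_csv([prof], pa)
        write_profiles_csv([prof], pb_)
        assert pa.read_bytes() == pb_.read_bytes()

    def test_empty_results_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_results_csv([], tmp_path / "x.csv")


class TestPymolMacro:
    def test_model_mode_colors_and_black_default(self, tmp_path):
        out = tmp_path / "model.pml"
        write_pymol_macro({24: 3, 30: 2}, "model", out)
        text = out.read_text()
        assert "color black, polymer" in text
        assert "color red, resi 24" in text
        assert "color green, resi 30" in text

    def test_value_ramp_orders_width_and_color(self, tmp_path):
        out = tmp_path / "kex.pml"
        write_pymol_macro({24: 1029.3, 30: 3750.2}, "kex", out)
        text = out.read_text()
        # residue 30 (larger kex) is redder (lower green) and wider
        g24 = float(text.split("disp_c24, [1.000, ")[1].split(",")[0])
        g30 = float(text.split("disp_c30, [1.000, ")[1].split(",")[0])
        assert g30 < g24
        w24 = float(text.split("stick_radius, ")[1].split(",")[0])
        w30 = float(text.split("stick_radius, ")[2].split(",")[0])
        assert w30 > w24

    def test_residue_missing_from_structure_skipped(self, tmp_path):
        out = tmp_path / "kex.pml"
        with pytest.warns(UserWarning):
            write_pymol_macro({24: 1.0, 99: 2.0}, "kex", out, pdb_residues={24})
        text = out.read_text()
        assert "resi 24" in text and "resi 99" not in text

    def test_empty_values_warn(self, tmp_path):
        out = tmp_path / "empty.pml"
        with pytest.warns(UserWarning):
            write_pymol_macro({}, "rex", out)
        assert "color black, polymer" in out.read_text()


def test_project_config_round_trip(tmp_path):
    cfg = ProjectConfig(
        t_cpmg=0.08,
        fields=[
            {
                "frequency_mhz": 600.0,
                "vd_list": "vd.txt",
                "peak_lists": ["a.tsv", "b.tsv"],
            }
        ],
        seed=3,
    )
    path = tmp_path / "project.yaml"
    cfg.to_yaml(path)
    back = ProjectConfig.from_yaml(path)
    assert back.t_cpmg == 0.08 and back.seed == 3
    assert back.fields[0]["peak_lists"] == ["a.tsv", "b.tsv"]


def test_project_config_validation(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("t_cpmg: 0.08\nfields:\n- frequency_mhz: 600\n  vd_list: v\n  peak_lists: []\n")
    with pytest.raises(ValueError):
        ProjectConfig.from_yaml(path)
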