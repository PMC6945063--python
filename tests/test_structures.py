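"""Structure, parameter, and trajectory I/O contracts."""
import numpy as np
import pytest

from phosbind.structures import (Atom, ParamStructure, ParseError, Selection,
                                 Trajectory, assign_parameters,
                                 load_bundled_parameters, read_pdb, read_pqr,
                                 read_trajectory, write_bfactor_map, write_pdb,
                                 write_pqr, write_trajectory_pdb,
                                 write_trajectory_tsv)

from conftest import TOY_PDB, TWO_MODEL_PDB, make_peptide


class TestPDB:
    def test_roundtrip_preserves_atoms(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        s = read_pdb(p)
        assert len(s) == 3
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]
        assert np.allclose(s.atoms[1].xyz, [1.45, 0.0, 0.0])
        # write/read round-trip preserves coordinates to PDB precision
        q = tmp_path / "out.pdb"
        write_pdb(s, q)
        s2 = read_pdb(q)
        assert np.allclose(s.coords, s2.coords, atol=5e-4)

    def test_multi_model_returns_first_with_warning(self, tmp_path, caplog):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_MODEL_PDB)
        with caplog.at_level("WARNING"):
            s = read_pdb(p)
        assert len(s) == 1
        assert np.allclose(s.atoms[0].xyz, [0, 0, 0])
        assert any("MODEL" in r.message for r in caplog.records)

    def test_malformed_coordinate_names_line(self, tmp_path):
        bad = TOY_PDB.replace("       1.450", "      xx.450")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(ParseError, match="line 3"):
            read_pdb(p)

    def test_empty_structure_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("TITLE     nothing\nEND\n")
        with pytest.raises(ParseError):
            read_pdb(p)


class TestPQR:
    def test_single_line_field_mapping(self, tmp_path):
        p = tmp_path / "ion.pqr"
        p.write_text("ATOM 1 Q ION 1 0.0 0.0 0.0 1.0 2.0\n")
        s = read_pqr(p)
        assert len(s) == 1
        a = s.atoms[0]
        assert a.charge == 1.0 and a.radius == 2.0 and a.chain_id == "A"

    def test_roundtrip_identity(self, tmp_path, ala_ser_ala):
        s = assign_parameters(ala_ser_ala)
        p = tmp_path / "pep.pqr"
        write_pqr(s, p)
        s2 = read_pqr(p)
        assert np.allclose(s.coords, s2.coords)
        assert np.allclose(s.charges, s2.charges)
        assert np.allclose(s.radii, s2.radii)
        assert [a.name for a in s.atoms] == [a.name for a in s2.atoms]

    def test_negative_radius_rejected(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 Q ION 1 0.0 0.0 0.0 1.0 -2.0\n")
        with pytest.raises(ParseError):
            read_pqr(p)


class TestAssignParameters:
    def test_neutral_tripeptide(self, gly_tripeptide):
        s = assign_parameters(gly_tripeptide)
        assert abs(s.total_charge()) < 1e-9
        assert all(a.radius > 0 for a in s.atoms)

    def test_sep_net_charge_matches_table_sum(self):
        # oracle: direct column sum over the bundled parameter file
        table = load_bundled_parameters()
        sep_sum = sum(v[0] for (res, _), v in table.entries.items() if res == "SEP")
        assert sep_sum == pytest.approx(-2.0, abs=1e-9)

    def test_unknown_residue_listed_in_error(self, gly_tripeptide):
        bad = gly_tripeptide.copy()
        for a in bad.atoms:
            if a.res_seq == 2:
                a.res_name = "XYZ"
        with pytest.raises(KeyError, match="XYZ"):
            assign_parameters(bad)

    def test_idempotent(self, ala_ser_ala):
        s1 = assign_parameters(ala_ser_ala)
        s2 = assign_parameters(s1)
        assert np.allclose(s1.charges, s2.charges)
        assert np.allclose(s1.radii, s2.radii)


class TestTrajectoryIO:
    def test_multi_model_pdb(self, tmp_path, gly_tripeptide):
        frames = [gly_tripeptide.coords + i for i in range(3)]
        traj = Trajectory(gly_tripeptide, frames, [0.0, 1.0, 2.0])
        p = tmp_path / "traj.pdb"
        write_trajectory_pdb(traj, p)
        t2 = read_trajectory(p, gly_tripeptide)
        assert len(t2) == 3
        assert np.allclose(t2.frames[2], frames[2], atol=5e-4)

    def test_missing_atom_names_frame(self, tmp_path, gly_tripeptide):
        frames = [gly_tripeptide.coords, gly_tripeptide.coords]
        traj = Trajectory(gly_tripeptide, frames, [0.0, 1.0])
        p = tmp_path / "traj.tsv"
        write_trajectory_tsv(traj, p)
        lines = p.read_text().strip().split("\n")
        # drop one atom from frame 1 (the second frame)
        del lines[1 + len(gly_tripeptide) + 2]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="frame 1"):
            read_trajectory(p, gly_tripeptide)

    def test_tsv_roundtrip_bitwise(self, tmp_path, gly_tripeptide):
        rng = np.random.default_rng(0)
        frames = [gly_tripeptide.coords + rng.normal(size=(len(gly_tripeptide), 3))
                  for _ in range(2)]
        traj = Trajectory(gly_tripeptide, frames, [0.0, 10.0])
        p = tmp_path / "traj.tsv"
        write_trajectory_tsv(traj, p)
        t2 = read_trajectory(p, gly_tripeptide)
        for f1, f2 in zip(traj.frames, t2.frames):
            assert np.array_equal(f1, f2)          # repr round-trip is exact
        assert np.array_equal(traj.times, t2.times)


class TestBfactorMap:
    def test_values_written_per_residue(self, tmp_path, gly_tripeptide):
        p = tmp_path / "bf.pdb"
        write_bfactor_map(gly_tripeptide, {("A", 1): 1.5}, p)
        s = read_pdb(p)
        for line in p.read_text().splitlines():
            if line.startswith("ATOM") and " A   1 " in line:
                assert line[60:66] == "  1.50"

    def test_clamping_logged(self, tmp_path, gly_tripeptide, caplog):
        p = tmp_path / "bf.pdb"
        with caplog.at_level("WARNING"):
            write_bfactor_map(gly_tripeptide, {("A", 2): 12345.0}, p)
        assert any("clamped" in r.message for r in caplog.records)
        for line in p.read_text().splitlines():
            if line.startswith("ATOM") and " A   2 " in line:
                assert line[60:66] == "999.99"

    def test_unknown_residue_errors(self, tmp_path, gly_tripeptide):
        with pytest.raises(KeyError):
            write_bfactor_map(gly_tripeptide, {("B", 9): 1.0}, tmp_path / "x.pdb")

    def test_reread_recovers_values(self, tmp_path, gly_tripeptide):
        p = tmp_path / "bf.pdb"
        write_bfactor_map(gly_tripeptide, {("A", 1): -3.21, ("A", 3): 7.77}, p)
        vals = {}
        for line in p.read_text().splitlines():
            if line.startswith("ATOM"):
                vals.setdefault(int(line[22:26]), float(line[60:66]))
        assert vals[1] == pytest.approx(-3.21, abs=0.005)
        assert vals[3] == pytest.approx(7.77, abs=0.005)


class TestSelection:
    def test_sidechain_heavy(self, ala_ser_ala):
        sel = Selection.sidechain_heavy(ala_ser_ala, "A", 2)
        names = {ala_ser_ala.atoms[i].name for i in sel.indices}
        assert names == {"CB", "OG"}

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            Selection(np.array([0, 0, 1]))
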