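"""Structure container, PDB round-trips, and the poly-Leucine conversion."""

import numpy as np
import pytest

from threebop.errors import FormatError, StructureError, UsageError
from threebop.fixtures import build_fixture_pose, build_helix
from threebop.geometry import dihedral_deg
from threebop.structure import (Pose, mutate_to_polyleu, read_pdb,
                                write_pdb)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.003   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       5.458   0.000   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       6.003   1.420   0.000  1.00  0.00           C
ATOM      7  N   ALA A   3       8.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  ALA A   3       9.458   0.000   0.000  1.00  0.00           C
ATOM      9  C   ALA A   3      10.003   1.420   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.003   1.420   0.000  1.00  0.00           C
ATOM      4  OG ASER A   1       3.000   3.000   0.000  0.60  0.00           O
ATOM      5  OG BSER A   1       3.500   3.500   0.000  0.40  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


class TestReadPdb:
    def test_minimal_three_residues(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        pose = read_pdb(path)
        assert pose.n_res == 3
        assert [r.name for r in pose.residues] == ["ALA", "GLY", "ALA"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        pose = read_pdb(path)
        og = pose.residues[0].atom("OG")
        np.testing.assert_allclose(og.position, [3.0, 3.0, 0.0])
        assert sum(1 for a in pose.residues[0].atoms if a.name == "OG") == 1

    def test_water_only_file_is_format_error(self, tmp_path):
        path = tmp_path / "wat.pdb"
        path.write_text(WATER_ONLY_PDB)
        with pytest.raises(FormatError):
            read_pdb(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises((FormatError, OSError)):
            read_pdb(tmp_path / "absent.pdb")


class TestWritePdb:
    def test_round_trip_preserves_structure(self, tmp_path):
        pose = build_fixture_pose("two_helix_bundle", 0)
        path = tmp_path / "bundle.pdb"
        write_pdb(pose, path)
        back = read_pdb(path)
        orig = list(pose.all_atoms())
        rt = list(back.all_atoms())
        assert len(orig) == len(rt)
        for a, b in zip(orig, rt):
            assert a.name == b.name
            assert a.res_index == b.res_index
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_ter_between_chains(self, tmp_path):
        pose = build_fixture_pose("two_helix_bundle", 0)
        path = tmp_path / "bundle.pdb"
        write_pdb(pose, path)
        lines = path.read_text().splitlines()
        ter_indices = [i for i, ln in enumerate(lines)
                       if ln.startswith("TER")]
        chain_b_start = next(i for i, ln in enumerate(lines)
                             if ln.startswith("ATOM") and ln[21] == "B")
        assert any(i < chain_b_start for i in ter_indices)

    def test_empty_pose_raises(self, tmp_path):
        with pytest.raises(StructureError):
            write_pdb(Pose([], []), tmp_path / "empty.pdb")


class TestPolyLeu:
    def test_helix_becomes_leucine(self):
        pose = build_helix(10, res_name="ALA")
        out = mutate_to_polyleu(pose)
        assert all(r.name == "LEU" for r in out.residues)
        for res in out.residues:
            names = {a.name for a in res.sidechain_atoms}
            assert {"CB", "CG", "CD1", "CD2"} <= names

    def test_chi_angles(self):
        out = mutate_to_polyleu(build_helix(4))
        for res in out.residues:
            chi1 = dihedral_deg(res.atom("N").position,
                                res.atom("CA").position,
                                res.atom("CB").position,
                                res.atom("CG").position) % 360.0
            chi2 = dihedral_deg(res.atom("CA").position,
                                res.atom("CB").position,
                                res.atom("CG").position,
                                res.atom("CD1").position) % 360.0
            assert chi1 == pytest.approx(240.0, abs=0.1)
            assert chi2 == pytest.approx(120.0, abs=0.1)

    def test_glycine_untouched(self):
        pose = build_helix(5, res_name="GLY")
        out = mutate_to_polyleu(pose)
        assert all(r.name == "GLY" for r in out.residues)
        assert all(not r.sidechain_atoms for r in out.residues)

    def test_idempotent_and_backbone_fixed(self):
        pose = build_helix(6)
        once = mutate_to_polyleu(pose)
        twice = mutate_to_polyleu(once)
        for a, b in zip(once.all_atoms(), twice.all_atoms()):
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)
        for orig_res, new_res in zip(pose.residues, once.residues):
            for name in ("N", "CA", "C"):
                np.testing.assert_allclose(
                    orig_res.atom(name).position,
                    new_res.atom(name).position, atol=0.0)

    def test_missing_backbone_atom_raises(self):
        pose = build_helix(3)
        pose.residues[1].backbone_atoms = [
            a for a in pose.residues[1].backbone_atoms if a.name != "CA"]
        with pytest.raises(StructureError, match="2"):
            mutate_to_polyleu(pose)


class TestFixtures:
    @pytest.mark.parametrize("spec", ["glu_two_ser", "buried_triad",
                                      "two_helix_bundle", "surface_polar"])
    def test_deterministic(self, spec):
        a = build_fixture_pose(spec, 0)
        b = build_fixture_pose(spec, 0)
        for x, y in zip(a.all_atoms(), b.all_atoms()):
            np.testing.assert_array_equal(x.position, y.position)

    def test_unknown_spec(self):
        with pytest.raises(UsageError):
            build_fixture_pose("bogus", 0)

    def test_no_duplicate_coordinates(self):
        pose = build_fixture_pose("glu_two_ser", 0)
        coords = np.array([a.position for a in pose.all_atoms()])
        from scipy.spatial.distance import pdist
        assert pdist(coords).min() > 1e-6
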