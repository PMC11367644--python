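"""Structure module: parsing, superposition, RMSF, contact detection."""

import numpy as np
import pytest

from clawkit import structure, synthetic
from clawkit.structure import (
    StructureModel,
    contact_number_profile,
    detect_contacts,
    detect_hbonds,
    interface_report,
    kabsch_superpose,
    pair_ca_atoms,
    pocket_residues,
    read_pdb,
    rmsf_per_atom,
)
from clawkit.structure.model import Atom

from conftest import random_rotation
from oracles import quaternion_rmsd

ALTLOC_PDB = """\
ATOM      1  N  AALA A   1      11.104   6.134  -6.504  0.60 10.00           N
ATOM      2  N  BALA A   1      11.804   6.134  -6.504  0.40 10.00           N
ATOM      3  CA  ALA A   1      12.560   6.071  -6.507  1.00 10.00           C
ATOM      4  C   ALA A   1      13.075   6.267  -7.928  1.00 10.00           C
ATOM      5  O   ALA A   1      12.731   7.259  -8.568  1.00 10.00           O
END
"""

SEP_PDB = """\
HETATM    1  N   SEP B 123      10.000  10.000  10.000  1.00 15.00           N
HETATM    2  CA  SEP B 123      11.450  10.000  10.000  1.00 15.00           C
HETATM    3  CB  SEP B 123      12.000  11.300  10.500  1.00 15.00           C
HETATM    4  OG  SEP B 123      12.200  12.200   9.500  1.00 15.00           O
HETATM    5  P   SEP B 123      12.500  13.700   9.900  1.00 15.00           P
HETATM    6  O1P SEP B 123      12.600  14.500   8.700  1.00 15.00           O
HETATM    7  O2P SEP B 123      11.400  14.200  10.800  1.00 15.00           O
HETATM    8  O3P SEP B 123      13.800  13.700  10.600  1.00 15.00           O
END
"""


class TestPdbReading:
    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_pdb(path)
        n_atoms = [a for a in model.atoms if a.name == "N"]
        assert len(n_atoms) == 1
        assert n_atoms[0].x == pytest.approx(11.104)  # the 0.60 conformer

    def test_sep_parsed_with_phosphate_atoms(self, tmp_path):
        path = tmp_path / "sep.pdb"
        path.write_text(SEP_PDB)
        model = read_pdb(path)
        names = {a.name for a in model.atoms if a.resn == "SEP"}
        assert {"P", "O1P", "O2P", "O3P"} <= names
        assert model.atoms[0].resi == 123  # author numbering preserved

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "nope.pdb")

    def test_roundtrip_read_write_read(self, tmp_path, toy_complex):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        toy_complex.write_pdb(p1)
        once = read_pdb(p1)
        once.write_pdb(p2)
        twice = read_pdb(p2)
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-12)


class TestSelections:
    def test_chain_and_residue_range_and_name(self, toy_complex):
        idx = toy_complex.select("chain A and resi 1-3 and name CA")
        atoms = [toy_complex.atoms[int(i)] for i in idx]
        assert len(atoms) == 3
        assert all(a.name == "CA" and a.chain == "A" for a in atoms)

    def test_resn_selection(self, toy_complex):
        idx = toy_complex.select("resn SEP")
        assert all(toy_complex.atoms[int(i)].resn == "SEP" for i in idx)
        assert len(idx) == 10

    def test_unknown_keyword_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            toy_complex.select("within 5 of chain B")


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 3))
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        assert kabsch_superpose(moved, pts).rmsd < 1e-9

    def test_matches_quaternion_oracle_on_random_sets(self):
        """100 random instances, sizes 3-50, against the Horn oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            assert abs(kabsch_superpose(a, b).rmsd - quaternion_rmsd(a, b)) < 1e-9

    def test_single_displaced_atom_matches_oracle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])
        moved = pts.copy()
        moved[4, 2] += 1.0
        assert abs(
            kabsch_superpose(moved, pts).rmsd - quaternion_rmsd(moved, pts)
        ) < 1e-9

    def test_proper_rotation_enforced(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirror image
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0.1  # reflection not available

    def test_degenerate_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestCaPairing:
    def test_identical_models_pair_all(self, toy_complex):
        ca, cb, report = pair_ca_atoms(toy_complex, toy_complex)
        assert report["matched"] == 13  # 8 domain + 5 peptide residues
        assert report["unmatched_a"] == 0

    def test_missing_residues_reduce_matches(self, toy_complex):
        keep = toy_complex.select("chain A and resi 1-5")
        trimmed_a = toy_complex.subset(
            np.concatenate([keep, toy_complex.select("chain B")])
        )
        _, _, report = pair_ca_atoms(trimmed_a, toy_complex)
        assert report["matched"] == 10
        assert report["unmatched_b"] == 3

    def test_chain_mapping_equivalent_to_rename(self, toy_complex):
        renamed = StructureModel(
            [
                Atom("C" if a.chain == "A" else "D", a.resi, a.icode, a.resn,
                     a.name, a.element, a.x, a.y, a.z, a.occupancy, a.bfactor,
                     a.het)
                for a in toy_complex.atoms
            ]
        )
        _, _, direct = pair_ca_atoms(toy_complex, toy_complex)
        _, _, mapped = pair_ca_atoms(
            toy_complex, renamed, chain_map={"A": "C", "B": "D"}
        )
        assert mapped["matched"] == direct["matched"]


class TestRmsf:
    def test_identical_frames_zero_rmsf(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(20, 3))
        rmsf = rmsf_per_atom([frame, frame, frame])
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-12)

    def test_single_oscillating_atom_closed_form(self):
        """One atom at +/-d along z over two frames: RMSF = d for it."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 3)) * 5
        d = 0.7
        f1, f2 = base.copy(), base.copy()
        f1[9, 2] += d
        f2[9, 2] -= d
        rmsf = rmsf_per_atom([f1, f2], fit_indices=np.arange(9))
        np.testing.assert_allclose(rmsf[:9], 0.0, atol=1e-9)
        assert rmsf[9] == pytest.approx(d, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(2)
        frames = [rng.normal(size=(15, 3)) for _ in range(4)]
        ref = rmsf_per_atom(frames, superpose_to="mean")
        rot = random_rotation(rng)
        rotated = [f @ rot.T + np.array([3.0, 0.0, -1.0]) for f in frames]
        np.testing.assert_allclose(
            rmsf_per_atom(rotated, superpose_to="mean"), ref, atol=1e-9
        )

    def test_inconsistent_frames_rejected(self):
        with pytest.raises(ValueError):
            rmsf_per_atom([np.zeros((4, 3)), np.zeros((5, 3))])


class TestHbonds:
    def test_zero_cutoff_empty(self, toy_complex):
        assert detect_hbonds(toy_complex, "chain A", "chain B", d_max=0.0) == []

    def test_group_swap_symmetry(self, toy_complex):
        ab = detect_hbonds(toy_complex, "chain A", "chain B")
        ba = detect_hbonds(toy_complex, "chain B", "chain A")
        pairs = lambda bonds: {
            frozenset([(h.donor.chain, h.donor.resi, h.donor.name),
                       (h.acceptor.chain, h.acceptor.resi, h.acceptor.name)])
            for h in bonds
        }
        assert pairs(ab) == pairs(ba)

    def test_monotone_in_cutoff(self, toy_complex):
        tight = detect_hbonds(toy_complex, "chain A", "chain B", d_max=2.0)
        loose = detect_hbonds(toy_complex, "chain A", "chain B", d_max=3.5)
        assert len(tight) <= len(loose)

    def test_rigid_motion_invariance(self, toy_complex):
        rng = np.random.default_rng(7)
        moved = toy_complex.transformed(random_rotation(rng), np.array([4.0, 5, 6]))
        assert len(detect_hbonds(moved, "chain A", "chain B")) == 5

    def test_overlapping_selections_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="disjoint"):
            detect_hbonds(toy_complex, "chain A", "chain A")


class TestContacts:
    def test_planted_lys_phosphate_salt_bridge_at_3A(self):
        """A Lys NZ / phosphate O pair at 3.0 A is one charge contact."""
        atoms = [
            Atom("A", 1, "", "LYS", "CE", "C", 0.0, 1.45, 0.0),
            Atom("A", 1, "", "LYS", "NZ", "N", 0.0, 0.0, 0.0),
            Atom("B", 9, "", "SEP", "O1P", "O", 0.0, -3.0, 0.0),
            Atom("B", 9, "", "SEP", "P", "P", 0.0, -4.5, 0.0),
        ]
        model = StructureModel(atoms)
        contacts = detect_contacts(model, "chain A", "chain B")
        assert len(contacts) == 1
        assert contacts[0].type == "charge_charge"
        assert contacts[0].distance == pytest.approx(3.0)

    def test_zero_cutoffs_empty(self, toy_complex):
        assert detect_contacts(toy_complex, "chain A", "chain B", 0.0, 0.0) == []

    def test_monotone_in_cutoff(self, toy_complex):
        small = detect_contacts(toy_complex, "chain A", "chain B", 4.0, 3.0)
        large = detect_contacts(toy_complex, "chain A", "chain B", 6.0, 5.0)
        assert len(small) <= len(large)


class TestPocket:
    def test_single_atom_within_cutoff(self, toy_complex):
        res = pocket_residues(toy_complex, "chain B and resi 104 and name CG1",
                              cutoff=4.4, receptor_selection="chain A")
        assert [r["resi"] for r in res] == [4]
        assert res[0]["min_distance_A"] == pytest.approx(4.0)

    def test_cutoff_below_closest_distance_empty(self, toy_complex):
        res = pocket_residues(toy_complex, "chain B and resi 104 and name CG1",
                              cutoff=3.0, receptor_selection="chain A")
        assert res == []

    def test_enlarging_cutoff_never_removes(self, toy_complex):
        small = pocket_residues(toy_complex, "chain B", cutoff=3.5,
                                receptor_selection="chain A")
        large = pocket_residues(toy_complex, "chain B", cutoff=5.0,
                                receptor_selection="chain A")
        small_keys = {(r["chain"], r["resi"]) for r in small}
        large_keys = {(r["chain"], r["resi"]) for r in large}
        assert small_keys <= large_keys


class TestContactProfile:
    def test_pull_apart_counts_nonincreasing_to_zero(self, toy_complex):
        frames, dcoms = [], []
        pep = toy_complex.select("chain B")
        for step, shift in enumerate(np.linspace(0, 30, 8)):
            xyz = toy_complex.coords.copy()
            xyz[pep, 2] += shift
            frame = toy_complex.with_coords(xyz)
            frames.append(frame)
            dcoms.append(10.0 + shift)
        df = contact_number_profile(frames, "chain A", "chain B", cutoff=4.5,
                                    d_com=dcoms)
        counts = df["contact_count"].to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert counts[-1] == 0

    def test_separated_groups_zero(self, toy_complex):
        pep = toy_complex.select("chain B")
        xyz = toy_complex.coords.copy()
        xyz[pep, 1] += 100.0
        frame = toy_complex.with_coords(xyz)
        df = contact_number_profile([frame], "chain A", "chain B", d_com=[50.0])
        assert df["contact_count"].iloc[0] == 0

    def test_overlapping_identical_groups_n_squared(self):
        atoms = [Atom("A", 1, "", "ALA", f"C{i}", "C", *xyz)
                 for i, xyz in enumerate([(0, 0, 0), (0, 0, 0), (0, 0, 0)])]
        atoms += [Atom("B", 2, "", "ALA", f"C{i}", "C", *xyz)
                  for i, xyz in enumerate([(0, 0, 0), (0, 0, 0), (0, 0, 0)])]
        model = StructureModel(atoms)
        df = contact_number_profile([model], "chain A", "chain B",
                                    cutoff=1.0, d_com=[0.0])
        assert df["contact_count"].iloc[0] == 9

    def test_missing_dcom_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="d_com"):
            contact_number_profile([toy_complex], "chain A", "chain B")


class TestInterfaceReport:
    def test_lists_exactly_planted_interactions(self, toy_complex):
        text = interface_report(toy_complex, "chain A", "chain B")
        assert text.count("H-bond") == 5
        assert text.count("(charge_charge)") == 1
        assert text.count("(hydrophobic)") == 1

    def test_empty_peptide_selection_marked(self, toy_complex):
        text = interface_report(toy_complex, "chain A", "resi 999")
        assert "no contacts" in text

    def test_byte_identical_reruns(self, toy_complex):
        a = interface_report(toy_complex, "chain A", "chain B")
        b = interface_report(toy_complex, "chain A", "chain B")
        assert a == b
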