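import numpy as np
import pytest

from rigidall.geometry import angle
from rigidall.structure import (AtomRecord, Ensemble, FormatError,
                                ResidueKey, StructureModel, TopologyError,
                                add_polar_hydrogens, read_ensemble,
                                read_structure, select_neighborhood,
                                write_structure)

from conftest import simple_atom, tripeptide

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.095  -4.969  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   2.000   3.000  1.00  0.00           C
ENDMDL
END
"""


class TestReadStructure:
    def test_three_atom_echo(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(THREE_ATOM_PDB)
        model = read_structure(path)
        assert len(model) == 3
        assert model.atoms[0].xyz == (11.104, 6.134, -6.504)
        assert model.atoms[2].name == "C"
        assert model.atoms[0].res_name == "ALA"

    def test_model_selection(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_MODEL_PDB)
        model2 = read_structure(path, model_index=2)
        assert model2.atoms[0].xyz == (1.0, 2.0, 3.0)

    def test_missing_model_raises(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_MODEL_PDB)
        with pytest.raises((IndexError, FormatError)):
            read_structure(path, model_index=5)

    def test_unparseable_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM  garbage line that is not fixed width\n")
        with pytest.raises((FormatError, ValueError)):
            read_structure(path)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        model = tripeptide()
        path = tmp_path / "tri.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert len(back) == len(model)
        np.testing.assert_allclose(np.round(model.coords, 3), back.coords,
                                   atol=5e-4)
        assert [a.name for a in back.atoms] == [a.name for a in model.atoms]


    def test_reads_mmcif(self, tmp_path):
        import biotite.structure.io.pdbx as bt_pdbx

        model = tripeptide()
        from rigidall.structure import _to_atom_array

        cif = bt_pdbx.CIFFile()
        bt_pdbx.set_structure(cif, _to_atom_array(model))
        path = tmp_path / "tri.cif"
        cif.write(str(path))
        back = read_structure(path)
        assert len(back) == len(model)
        np.testing.assert_allclose(back.coords, model.coords, atol=5e-3)


class TestReadEnsemble:
    def test_single_model(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(THREE_ATOM_PDB)
        ens = read_ensemble(path)
        assert len(ens) == 1

    def test_generator_roundtrip(self, tmp_path):
        from rigidall.synthetic import gen_dihedral_ensemble

        ens, _ = gen_dihedral_ensemble(10, 6, seed=3)
        path = tmp_path / "ens.pdb"
        write_structure(ens, path)
        back = read_ensemble(path)
        assert len(back) == 10
        for a, b in zip(ens.frames, back.frames):
            np.testing.assert_allclose(np.round(a.coords, 3), b.coords,
                                       atol=5e-4)

    def test_topology_mismatch_raises(self, tmp_path):
        text = TWO_MODEL_PDB.replace(
            "ATOM      2  CA  GLY A   2       4.800   2.000   3.000"
            "  1.00  0.00           C\n", "", 1)
        path = tmp_path / "broken.pdb"
        path.write_text(text)
        with pytest.raises(TopologyError):
            read_ensemble(path)


class TestAtomRecord:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            simple_atom(1, "CA", "C", (np.nan, 0, 0))

    def test_empty_element_rejected(self):
        with pytest.raises(ValueError):
            simple_atom(1, "CA", "", (0, 0, 0))


class TestAddPolarHydrogens:
    def test_tripeptide_backbone_count(self):
        model = tripeptide()
        out = add_polar_hydrogens(model)
        added = [a for a in out.atoms if a.element == "H"]
        # N-terminus excluded: exactly n_res - 1 backbone amide hydrogens
        assert len(added) == 2
        assert all(a.name == "H" for a in added)

    def test_proline_gets_no_backbone_h(self):
        model = tripeptide(("ALA", "PRO", "ALA"))
        out = add_polar_hydrogens(model)
        h_res = [a.res_seq for a in out.atoms if a.element == "H"]
        assert 2 not in h_res

    def test_amide_h_bisects_external_angle(self):
        model = tripeptide()
        out = add_polar_hydrogens(model)
        key = ResidueKey("A", 2)
        h = out.atom_coord(key, "H")
        n = out.atom_coord(key, "N")
        ca = out.atom_coord(key, "CA")
        c_prev = out.atom_coord(ResidueKey("A", 1), "C")
        assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=1e-9)
        assert angle(c_prev, n, h) == pytest.approx(angle(ca, n, h),
                                                    abs=1e-6)

    def test_idempotent(self):
        model = tripeptide()
        once = add_polar_hydrogens(model)
        twice = add_polar_hydrogens(once)
        assert len(twice) == len(once)
        np.testing.assert_allclose(twice.coords, once.coords)

    def test_sidechain_donor_h(self):
        from rigidall.synthetic import gen_ideal_helix
        from rigidall.mutation import MutationSpec, apply_point_mutation

        ref, _ = gen_ideal_helix(8)
        mutant = apply_point_mutation(
            ref, MutationSpec(ResidueKey("A", 4), "ALA", "SER"))
        out = add_polar_hydrogens(mutant)
        names = {a.name for a in out.atoms if a.res_seq == 4}
        assert "HG" in names  # serine hydroxyl hydrogen


class TestSelectNeighborhood:
    def _toy(self, d1, d2):
        atoms = [
            simple_atom(1, "C1", "C", (0, 0, 0), res_seq=99,
                        res_name="LIG", hetero=True),
            simple_atom(2, "CA", "C", (d1, 0, 0), res_seq=1),
            simple_atom(3, "CA", "C", (d2, 0, 0), res_seq=2, chain="B"),
        ]
        return StructureModel(atoms)

    def test_radius_zero_empty(self):
        model = self._toy(2.9, 3.1)
        sel = select_neighborhood(model, ResidueKey("A", 99), 0.0)
        assert sel.atom_ids == []

    def test_boundary_closed_interval(self):
        model = self._toy(2.9, 3.1)
        sel = select_neighborhood(model, ResidueKey("A", 99), 3.0)
        assert sel.atom_ids == [1]
        assert sel.residues == {ResidueKey("A", 1)}
        sel_inc = select_neighborhood(model, ResidueKey("A", 99), 3.1)
        assert sel_inc.atom_ids == [1, 2]

    def test_matches_brute_force(self, rng):
        atoms = [simple_atom(1, "L1", "C", rng.uniform(-5, 5, 3),
                             res_seq=500, res_name="LIG", hetero=True),
                 simple_atom(2, "L2", "C", rng.uniform(-5, 5, 3),
                             res_seq=500, res_name="LIG", hetero=True)]
        for i in range(200):
            atoms.append(simple_atom(3 + i, "CA", "C",
                                     rng.uniform(-15, 15, 3),
                                     res_seq=i + 1))
        model = StructureModel(atoms)
        lig = ResidueKey("A", 500)
        lig_idx = model.residue_atoms(lig)
        radius = 6.0
        sel = select_neighborhood(model, lig, radius)
        expect = []
        for i in range(len(model)):
            if i in lig_idx:
                continue
            d = min(np.linalg.norm(model.coords[i] - model.coords[j])
                    for j in lig_idx)
            if d <= radius:
                expect.append(i)
        assert sel.atom_ids == expect

    def test_monotone_in_radius(self, rng):
        model = self._toy(2.0, 4.0)
        lig = ResidueKey("A", 99)
        for r1, r2 in [(0.5, 1.0), (1.0, 3.0), (3.0, 5.0)]:
            s1 = set(select_neighborhood(model, lig, r1).atom_ids)
            s2 = set(select_neighborhood(model, lig, r2).atom_ids)
            assert s1 <= s2

    def test_unknown_ligand_raises(self):
        model = self._toy(1, 2)
        with pytest.raises(KeyError):
            select_neighborhood(model, ResidueKey("Z", 1), 3.0)


def test_ensemble_invariant_checked():
    model_a = tripeptide()
    atoms_b = model_a.atoms[:-1]
    model_b = StructureModel(atoms_b)
    with pytest.raises(TopologyError):
        Ensemble([model_a, model_b])


def test_ligand_synonyms():
    atoms = [simple_atom(1, "PA", "P", (0, 0, 0), res_seq=601,
                         res_name="NAI", hetero=True)]
    model = StructureModel(atoms)
    assert model.find_ligand("NADH") == [ResidueKey("A", 601)]
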