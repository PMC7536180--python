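import numpy as np
import pytest

from rigidall.compare import (DegeneracyError, backbone_dihedrals,
                              buried_interface_area, diff_interactions,
                              helix_rotation_angle, interaction_network,
                              per_residue_ca_rmsd, residue_pair_distances,
                              superpose)
from rigidall.geometry import rotation_about_axis
from rigidall.structure import (AtomRecord, ResidueKey, StructureModel,
                                add_polar_hydrogens)
from rigidall.synthetic import gen_dihedral_ensemble, gen_ideal_helix

from conftest import simple_atom


@pytest.fixture(scope="module")
def helix_pair():
    return gen_ideal_helix(12)


class TestSuperpose:
    def test_identical_models(self, helix_pair):
        ref, _ = helix_pair
        result = superpose(ref, ref)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, helix_pair, rng):
        ref, _ = helix_pair
        R = rotation_about_axis([1.0, -2.0, 0.5], 25.0)
        t = np.array([4.0, -1.0, 2.0])
        moved = ref.transformed(R, t)
        result = superpose(ref, moved)
        assert result.rmsd == pytest.approx(0.0, abs=1e-8)
        from rigidall.geometry import rotation_angle

        assert rotation_angle(result.rotation) == pytest.approx(25.0,
                                                                abs=1e-6)

    def test_reflection_yields_proper_rotation(self, helix_pair):
        ref, _ = helix_pair
        mirrored = StructureModel([
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.chain,
                       a.res_seq, a.icode,
                       (-a.xyz[0], a.xyz[1], a.xyz[2]))
            for a in ref.atoms
        ])
        result = superpose(ref, mirrored)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0,
                                                               abs=1e-9)
        assert result.rmsd > 0.1  # reflection absorbed as residual

    def test_matches_scipy_oracle(self, helix_pair, rng):
        from scipy.spatial.transform import Rotation

        ref, _ = helix_pair
        R = rotation_about_axis(rng.normal(size=3), 73.0)
        moved = ref.transformed(R, rng.normal(size=3))
        mine = superpose(ref, moved)
        a = ref.coords - ref.coords.mean(axis=0)
        b = moved.coords - moved.coords.mean(axis=0)
        oracle, rssd = Rotation.align_vectors(a, b)
        np.testing.assert_allclose(mine.rotation, oracle.as_matrix(),
                                   atol=1e-6)

    def test_rmsd_invariant_to_rigid_pretransform(self, helix_pair, rng):
        ref, _ = helix_pair
        jittered = StructureModel([
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.chain,
                       a.res_seq, a.icode,
                       tuple(np.array(a.xyz) + rng.normal(0, 0.3, 3)))
            for a in ref.atoms
        ])
        base = superpose(ref, jittered).rmsd
        R = rotation_about_axis(rng.normal(size=3), 50.0)
        pre = jittered.transformed(R, rng.normal(size=3) * 5)
        assert superpose(ref, pre).rmsd == pytest.approx(base, abs=1e-8)

    def test_too_few_pairs_raises(self):
        atoms = [simple_atom(1, "CA", "C", (0, 0, 0), res_seq=1),
                 simple_atom(2, "CA", "C", (1, 0, 0), res_seq=2)]
        model = StructureModel(atoms)
        with pytest.raises(DegeneracyError):
            superpose(model, model)

    def test_collinear_raises(self):
        atoms = [simple_atom(i, "CA", "C", (float(i), 0, 0), res_seq=i)
                 for i in range(1, 6)]
        model = StructureModel(atoms)
        with pytest.raises(DegeneracyError):
            superpose(model, model)


class TestPerResidueRMSD:
    def test_identical_all_zero(self, helix_pair):
        ref, _ = helix_pair
        frame = superpose(ref, ref)
        profile = per_residue_ca_rmsd(ref, ref, frame)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in profile.per_residue.values())

    def test_displaced_residue_reports_displacement(self, helix_pair):
        ref, _ = helix_pair
        atoms = []
        for a in ref.atoms:
            xyz = a.xyz
            if a.res_seq == 12 and a.name == "CA":
                xyz = (xyz[0] + 2.0, xyz[1], xyz[2])
            atoms.append(AtomRecord(a.serial, a.name, a.element,
                                    a.res_name, a.chain, a.res_seq,
                                    a.icode, xyz))
        moved = StructureModel(atoms)
        core = [ResidueKey("A", i) for i in range(1, 11)]
        frame = superpose(ref, moved, selection=core)
        profile = per_residue_ca_rmsd(ref, moved, frame)
        assert profile.per_residue[ResidueKey("A", 12)] == pytest.approx(
            2.0, abs=1e-6)

    def test_permutation_invariant_to_atom_order(self, helix_pair, rng):
        ref, _ = helix_pair
        order = rng.permutation(len(ref.atoms))
        shuffled = StructureModel([ref.atoms[i] for i in order])
        frame = superpose(ref, shuffled)
        a = per_residue_ca_rmsd(ref, shuffled, frame).per_residue
        b = per_residue_ca_rmsd(ref, ref,
                                superpose(ref, ref)).per_residue
        assert set(a) == set(b)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)


class TestPairDistances:
    def test_three_four_five(self):
        atoms_a = [simple_atom(1, "X1", "C", (0, 0, 0), res_seq=1,
                               res_name="UNK"),
                   simple_atom(2, "X2", "C", (3, 4, 0), res_seq=2,
                               res_name="UNK")]
        model = StructureModel(atoms_a)
        table = residue_pair_distances(
            {"m": model}, [(ResidueKey("A", 1), ResidueKey("A", 2))])
        assert table.iloc[0]["m"] == pytest.approx(5.0)

    def test_brute_force_oracle(self, rng):
        atoms = []
        serial = 0
        for res in range(1, 7):
            for k in range(4):
                serial += 1
                atoms.append(simple_atom(serial, f"C{k}", "C",
                                         rng.uniform(-8, 8, 3),
                                         res_seq=res, res_name="UNK"))
        model = StructureModel(atoms)
        pairs = [(ResidueKey("A", 1), ResidueKey("A", 4)),
                 (ResidueKey("A", 2), ResidueKey("A", 6))]
        table = residue_pair_distances({"m": model}, pairs)
        for row_idx, (ka, kb) in enumerate(pairs):
            brute = min(
                np.linalg.norm(model.coords[i] - model.coords[j])
                for i in model.residue_atoms(ka)
                for j in model.residue_atoms(kb)
            )
            assert table.iloc[row_idx]["m"] == pytest.approx(brute)

    def test_ratio_with_two_models(self, helix_pair):
        ref, rot = gen_ideal_helix(8)
        table = residue_pair_distances(
            {"one": ref, "two": ref},
            [(ResidueKey("A", 1), ResidueKey("A", 5))])
        assert table.iloc[0]["ratio"] == pytest.approx(1.0)

    def test_unresolvable_pair_raises(self, helix_pair):
        ref, _ = helix_pair
        with pytest.raises(KeyError):
            residue_pair_distances(
                {"m": ref}, [(ResidueKey("A", 1), ResidueKey("B", 99))])


class TestBackboneDihedrals:
    def test_ideal_trans_peptide_omega(self):
        ens, _ = gen_dihedral_ensemble(1, 6, seed=0)
        model = ens.frames[0]
        phi, psi, omega = backbone_dihedrals(model, ResidueKey("A", 3))
        assert omega == pytest.approx(180.0, abs=1e-6) or \
            omega == pytest.approx(-180.0, abs=1e-6)

    def test_terminal_angles_undefined(self):
        ens, _ = gen_dihedral_ensemble(1, 6, seed=0)
        model = ens.frames[0]
        phi, psi, omega = backbone_dihedrals(model, ResidueKey("A", 1))
        assert phi is None and omega is None and psi is not None

    def test_mirror_negates_dihedrals(self):
        ens, _ = gen_dihedral_ensemble(1, 6, {3: [-73.0]}, seed=0)
        model = ens.frames[0]
        mirrored = StructureModel([
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.chain,
                       a.res_seq, a.icode,
                       (-a.xyz[0], a.xyz[1], a.xyz[2]))
            for a in model.atoms
        ])
        for res in (3, 4):
            key = ResidueKey("A", res)
            orig = backbone_dihedrals(model, key)
            flip = backbone_dihedrals(mirrored, key)
            for o, f in zip(orig, flip):
                if abs(abs(o) - 180.0) < 1e-6:
                    assert abs(abs(f) - 180.0) < 1e-6
                else:
                    assert f == pytest.approx(-o, abs=1e-6)


class TestHelixRotation:
    def test_identity_zero(self):
        ref, same = gen_ideal_helix(12, rotation_about_axis_deg=0.0)
        hr = helix_rotation_angle(ref, same, ("A", 1, 12), core=None)
        assert hr.angle == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("applied", [15.0, 20.1])
    def test_recovers_applied_rotation(self, applied):
        ref, rot = gen_ideal_helix(12, rotation_about_axis_deg=applied)
        hr = helix_rotation_angle(ref, rot, ("A", 1, 12), core=None)
        assert hr.angle == pytest.approx(applied, abs=0.5)

    def test_short_helix_raises(self):
        ref, rot = gen_ideal_helix(12)
        with pytest.raises(DegeneracyError):
            helix_rotation_angle(ref, rot, ("A", 1, 4), core=None)

    def test_sense_flips_with_direction(self):
        ref, plus = gen_ideal_helix(12, rotation_about_axis_deg=15.0)
        _, minus = gen_ideal_helix(12, rotation_about_axis_deg=-15.0)
        s1 = helix_rotation_angle(ref, plus, ("A", 1, 12), core=None).sense
        s2 = helix_rotation_angle(ref, minus, ("A", 1, 12), core=None).sense
        assert {s1, s2} == {"clockwise", "anticlockwise"}


class TestBuriedInterfaceArea:
    def test_far_ligand_zero(self):
        atoms = [simple_atom(1, "CA", "C", (0, 0, 0)),
                 simple_atom(2, "CB", "C", (1.5, 0, 0)),
                 simple_atom(3, "C1", "C", (50, 0, 0), res_seq=90,
                             res_name="LIG", hetero=True)]
        model = StructureModel(atoms)
        area = buried_interface_area(model, ResidueKey("A", 90))
        assert area.bsa == pytest.approx(0.0, abs=1e-9)

    def test_two_spheres_match_analytic_caps(self):
        # two carbon spheres: buried area from the spherical-cap formula
        from rigidall.chemdata import vdw_radius

        d = 3.0
        probe = 1.4
        r = vdw_radius("C") + probe
        atoms = [simple_atom(1, "CA", "C", (0, 0, 0)),
                 simple_atom(2, "C1", "C", (d, 0, 0), res_seq=90,
                             res_name="LIG", hetero=True)]
        model = StructureModel(atoms)
        area = buried_interface_area(model, ResidueKey("A", 90),
                                     probe=probe, n_points=4000)
        # each sphere loses a cap of height h = r - d/2
        h = r - d / 2.0
        analytic = 2.0 * (2.0 * np.pi * r * h)
        assert area.bsa == pytest.approx(analytic, rel=0.02)

    def test_nonnegative(self, rng):
        atoms = [simple_atom(i + 1, "CA", "C", rng.uniform(-4, 4, 3),
                             res_seq=i + 1) for i in range(8)]
        atoms.append(simple_atom(9, "C1", "C", rng.uniform(-4, 4, 3),
                                 res_seq=90, res_name="LIG", hetero=True))
        model = StructureModel(atoms)
        area = buried_interface_area(model, ResidueKey("A", 90),
                                     n_points=960)
        assert area.bsa >= -1e-9


class TestInteractionNetwork:
    def _hbond_pair_model(self):
        from test_network import ideal_hbond_atoms

        d, h, a, b = ideal_hbond_atoms()
        atoms = [
            simple_atom(1, "N", "N", d, res_seq=1),
            simple_atom(2, "H", "H", h, res_seq=1),
            simple_atom(3, "CA", "C", (-0.7, 1.2, 0.0), res_seq=1),
            simple_atom(4, "O", "O", a, res_seq=5),
            simple_atom(5, "C", "C", b, res_seq=5),
        ]
        return StructureModel(atoms)

    def test_lone_donor_acceptor_pair(self):
        edges = interaction_network(self._hbond_pair_model())
        hbonds = [e for e in edges if e.kind == "hbond"]
        assert len(hbonds) == 1

    def test_parallel_rings_pipi(self):
        atoms = []
        serial = 0
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        for res, z in ((1, 0.0), (2, 4.0)):
            for k, name in enumerate(ring_names):
                t = 2 * np.pi * k / 6
                serial += 1
                atoms.append(simple_atom(
                    serial, name, "C",
                    (1.39 * np.cos(t), 1.39 * np.sin(t), z),
                    res_seq=res, res_name="PHE"))
        model = StructureModel(atoms)
        edges = interaction_network(model)
        assert any(e.kind == "pipi" for e in edges)

    def test_diff_self_empty(self):
        model = self._hbond_pair_model()
        edges = interaction_network(model)
        assert diff_interactions(edges, edges).is_empty

    def test_diff_detects_lost_edge(self):
        model = self._hbond_pair_model()
        edges = interaction_network(model)
        diff = diff_interactions(edges, [])
        assert len(diff.only_in_a) == len(edges)
        assert diff.only_in_b == []
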