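import numpy as np
import pytest

from rigidall.network import (BarEdge, ConstraintNetwork,
                              build_constraint_network,
                              detect_covalent_bonds, dilution_series,
                              find_hydrogen_bonds, mayo_hbond_energy)
from rigidall.structure import (ResidueKey, StructureModel,
                                add_polar_hydrogens)
from rigidall.synthetic import gen_ideal_helix

from conftest import simple_atom


def ideal_hbond_atoms(d=2.8):
    """Donor-H...acceptor-base with every Mayo angular term at 1."""
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = np.array([d, 0.0, 0.0])  # theta = 180
    # phi = H-A-B at 109.5 degrees for the sp3/sp3 case
    t = np.radians(180.0 - 109.5)
    base = acceptor + 1.43 * np.array([np.cos(t), np.sin(t), 0.0])
    return donor, hydrogen, acceptor, base


class TestMayoEnergy:
    def test_ideal_geometry_gives_minus_v0(self):
        d, h, a, b = ideal_hbond_atoms()
        e = mayo_hbond_energy(d, h, a, b, "sp3", "sp3")
        assert e == pytest.approx(-8.0, abs=1e-9)

    def test_distance_gate(self):
        d, h, a, b = ideal_hbond_atoms()
        a10 = np.array([10.0, 0.0, 0.0])
        assert mayo_hbond_energy(d, h, a10, b + a10 - a) == 0.0

    def test_angle_gate_strict_at_90(self):
        donor = np.array([0.0, 0.0, 0.0])
        hydrogen = np.array([1.0, 0.0, 0.0])
        acceptor = hydrogen + np.array([0.0, 2.2, 0.0])  # theta exactly 90
        base = acceptor + np.array([0.0, 1.4, 0.0])
        assert mayo_hbond_energy(donor, hydrogen, acceptor, base) == 0.0

    def test_continuous_in_distance_and_decays(self):
        energies = []
        for d in np.linspace(2.8, 3.59, 40):
            donor, h, a, b = ideal_hbond_atoms(d)
            energies.append(mayo_hbond_energy(donor, h, a, b, "sp3", "sp3"))
        energies = np.array(energies)
        assert np.all(energies < 0)
        assert np.all(np.diff(energies) > 0)  # monotone towards 0-
        steps = np.abs(np.diff(energies))
        assert steps.max() < 0.5  # no jumps on the retained domain


class TestCovalentDetection:
    def test_single_alanine_heavy_bond_count(self):
        # template enumeration: N-CA, CA-C, C=O, CA-CB
        atoms = [
            simple_atom(1, "N", "N", (0.0, 0.0, 0.0)),
            simple_atom(2, "CA", "C", (1.46, 0.0, 0.0)),
            simple_atom(3, "C", "C", (2.0, 1.4, 0.0)),
            simple_atom(4, "O", "O", (3.2, 1.5, 0.0)),
            simple_atom(5, "CB", "C", (2.0, -0.8, 1.2)),
        ]
        edges = detect_covalent_bonds(StructureModel(atoms))
        assert len(edges) == 4

    def test_peptide_bond_locked(self):
        from conftest import tripeptide

        model = tripeptide()
        edges = detect_covalent_bonds(model)
        c1 = model.atom_index(ResidueKey("A", 1), "C")
        n2 = model.atom_index(ResidueKey("A", 2), "N")
        peptide = [e for e in edges
                   if {e.body_i, e.body_j} == {c1, n2}]
        assert len(peptide) == 1
        assert peptide[0].kind == "covalent_locked"
        assert peptide[0].bars == 6

    def test_disulfide_detected(self):
        atoms = [
            simple_atom(1, "CB", "C", (0.0, 0.0, 0.0), res_seq=1,
                        res_name="CYS"),
            simple_atom(2, "SG", "S", (1.8, 0.0, 0.0), res_seq=1,
                        res_name="CYS"),
            simple_atom(3, "SG", "S", (3.85, 0.0, 0.0), res_seq=2,
                        res_name="CYS"),
            simple_atom(4, "CB", "C", (5.6, 0.0, 0.0), res_seq=2,
                        res_name="CYS"),
        ]
        edges = detect_covalent_bonds(StructureModel(atoms))
        ss = [e for e in edges if {e.body_i, e.body_j} == {1, 2}]
        assert len(ss) == 1


class TestBuildNetwork:
    def _hbond_model(self):
        """One ideal backbone-like donor/acceptor pair across residues."""
        d, h, a, b = ideal_hbond_atoms()
        atoms = [
            simple_atom(1, "N", "N", d, res_seq=1),
            simple_atom(2, "H", "H", h, res_seq=1),
            simple_atom(3, "CA", "C", (-0.7, 1.2, 0.0), res_seq=1),
            simple_atom(4, "O", "O", a, res_seq=5),
            simple_atom(5, "C", "C", b, res_seq=5),
        ]
        return StructureModel(atoms)

    def test_cutoff_semantics(self):
        model = self._hbond_model()
        hbonds = find_hydrogen_bonds(model)
        assert len(hbonds) == 1
        energy = hbonds[0].energy
        assert energy < -1
        net_keep = build_constraint_network(model, hbond_cutoff=energy + .1)
        assert sum(e.kind == "hbond" for e in net_keep.edges) == 1
        net_drop = build_constraint_network(model, hbond_cutoff=energy - .1)
        assert sum(e.kind == "hbond" for e in net_drop.edges) == 0

    def test_edge_recount(self):
        ref, _ = gen_ideal_helix(10)
        model = add_polar_hydrogens(ref)
        covalent = detect_covalent_bonds(model)
        net = build_constraint_network(model, hbond_cutoff=-0.1)
        by_kind = {}
        for e in net.edges:
            by_kind.setdefault(
                "covalent" if e.kind.startswith("covalent") else e.kind, []
            ).append(e)
        assert len(by_kind["covalent"]) == len(covalent)
        pairs = [(min(e.body_i, e.body_j), max(e.body_i, e.body_j), e.kind)
                 for e in net.edges]
        assert len(pairs) == len(set(pairs))  # no duplicates

    def test_helix_has_backbone_hbonds(self):
        ref, _ = gen_ideal_helix(12)
        model = add_polar_hydrogens(ref)
        hbonds = find_hydrogen_bonds(model)
        assert len(hbonds) >= 4  # i, i+4 pattern

    def test_no_hydrogen_no_hbonds(self, caplog):
        ref, _ = gen_ideal_helix(12)
        with caplog.at_level("WARNING"):
            hbonds = find_hydrogen_bonds(ref)
        assert hbonds == []
        assert any("no hydrogens" in r.message for r in caplog.records)

    def test_empty_model_empty_network(self):
        net = ConstraintNetwork(0, [])
        assert net.n_bodies == 0


class TestNetworkContainer:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            BarEdge(1, 1, 5, "covalent_rotatable")

    def test_invalid_bars_rejected(self):
        with pytest.raises(ValueError):
            BarEdge(0, 1, 4, "covalent_rotatable")

    def test_duplicate_edge_rejected(self):
        edges = [BarEdge(0, 1, 5, "covalent_rotatable"),
                 BarEdge(1, 0, 5, "covalent_rotatable")]
        with pytest.raises(ValueError):
            ConstraintNetwork(2, edges)

    def test_tsv_roundtrip(self, tmp_path):
        edges = [BarEdge(0, 1, 5, "covalent_rotatable"),
                 BarEdge(1, 2, 5, "hbond", -1.25),
                 BarEdge(0, 2, 2, "hydrophobic")]
        net = ConstraintNetwork(3, edges)
        path = tmp_path / "net.tsv"
        net.to_tsv(path)
        back = ConstraintNetwork.from_tsv(path)
        assert back.n_bodies == 3
        assert [(e.body_i, e.body_j, e.bars, e.kind) for e in back.edges] \
            == [(e.body_i, e.body_j, e.bars, e.kind) for e in edges]
        assert back.edges[1].energy == pytest.approx(-1.25)


class TestDilution:
    def test_grid_count(self):
        ref, _ = gen_ideal_helix(8)
        model = add_polar_hydrogens(ref)
        series = dilution_series(model, 0.0, -2.0, 0.01)
        assert len(series.cutoffs) == 201

    def test_lrc_monotone_and_hbonds_nonincreasing(self):
        ref, _ = gen_ideal_helix(12)
        model = add_polar_hydrogens(ref)
        series = dilution_series(model, 0.0, -2.0, 0.1)
        assert np.all(np.diff(series.retained_hbonds) <= 0)
        assert np.all(np.diff(series.lrc_size) <= 0)

    def test_no_hbond_constant_series(self):
        ref, _ = gen_ideal_helix(8)  # no hydrogens -> no hbonds
        series = dilution_series(ref, 0.0, -1.0, 0.25)
        assert len(set(series.lrc_size.tolist())) == 1
        assert np.all(series.retained_hbonds == 0)


def test_single_hbond_removal_never_grows_lrc():
    from rigidall.rigidity import rigid_clusters

    ref, _ = gen_ideal_helix(10)
    model = add_polar_hydrogens(ref)
    net = build_constraint_network(model, hbond_cutoff=-0.1)
    base = rigid_clusters(net).lrc_size
    hbond_ids = [i for i, e in enumerate(net.edges) if e.kind == "hbond"]
    assert hbond_ids
    for drop in hbond_ids:
        pruned = ConstraintNetwork(
            net.n_bodies,
            [e for i, e in enumerate(net.edges) if i != drop],
            body_residues=net.body_residues,
        )
        assert rigid_clusters(pruned).lrc_size <= base
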