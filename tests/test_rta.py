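import numpy as np
import pytest

from rigidall.network import BarEdge, ConstraintNetwork
from rigidall.rigidity import rigid_clusters
from rigidall.rta import (RTAProfile, SiteDefinition, allosteric_auc,
                          call_hotspots, remove_bodies, rta_scan_profile,
                          rta_transmission)
from rigidall.structure import ResidueKey
from rigidall.synthetic import gen_allosteric_toy

from conftest import make_network


class TestTransmission:
    def test_disconnected_components_zero(self):
        net = make_network(4, [(0, 1, 5), (2, 3, 5)])
        res = rta_transmission(net,
                               SiteDefinition("a", np.array([0, 1])),
                               SiteDefinition("b", np.array([2, 3])))
        assert res.transmitted == 0

    @pytest.mark.parametrize("planted", [0, 1, 2, 3])
    def test_planted_transmission(self, planted):
        toy = gen_allosteric_toy(planted, 4)
        res = rta_transmission(toy.network, toy.site_a, toy.site_b)
        assert res.transmitted == planted
        assert res.dof_B_before >= planted

    @pytest.mark.parametrize("planted", [1, 2])
    def test_severed_variant_zero(self, planted):
        toy = gen_allosteric_toy(planted, 4)
        res = rta_transmission(toy.severed, toy.site_a, toy.site_b)
        assert res.transmitted == 0

    def test_redundant_bridge_bar_leaves_transmission_unchanged(self):
        toy = gen_allosteric_toy(1, 4)
        # parallel 2-bar tether across an already locked (6-bar) pair
        locked = next(e for e in toy.network.edges if e.bars == 6)
        augmented = ConstraintNetwork(
            toy.network.n_bodies,
            toy.network.edges + [BarEdge(locked.body_i, locked.body_j, 2,
                                         "hydrophobic")],
            body_residues=toy.network.body_residues,
        )
        res = rta_transmission(augmented, toy.site_a, toy.site_b)
        assert res.transmitted == 1

    def test_independent_flexible_linkers_zero(self):
        # A and B dangle from a rigid hub on separate flexible chains
        edges = [(0, 1, 6), (1, 2, 5), (2, 3, 5), (1, 4, 5), (4, 5, 5)]
        net = make_network(6, edges)
        site_a = SiteDefinition("a", np.array([2, 3]))
        site_b = SiteDefinition("b", np.array([4, 5]))
        res = rta_transmission(net, site_a, site_b)
        assert res.transmitted == 0
        # brute-force oracle: measure B DOF before/after inserting every
        # possible rigidifying 6-bar star over A
        from rigidall.rigidity import play_network

        base, _ = play_network(net)
        probe = base.copy()
        before = probe.collect_on(site_a.bodies.copy()) - 6  # warm check
        state = base.copy()
        dof_b_before = state.collect_on(site_b.bodies.copy()) - 6
        state2 = base.copy()
        state2.insert_edges(np.array([2]), np.array([3]),
                            np.array([6]))
        dof_b_after = state2.collect_on(site_b.bodies.copy()) - 6
        assert dof_b_before == dof_b_after

    def test_overlapping_sites_rejected(self):
        net = make_network(3, [(0, 1, 5), (1, 2, 5)])
        with pytest.raises(ValueError):
            rta_transmission(net, SiteDefinition("a", np.array([0, 1])),
                             SiteDefinition("b", np.array([1, 2])))

    def test_transmitted_nonnegative_on_random_toys(self, rng):
        for t in (0, 1, 2):
            toy = gen_allosteric_toy(t, 3)
            res = rta_transmission(toy.network, toy.site_a, toy.site_b)
            assert res.transmitted >= 0

    def test_lrc_target_receives_nothing(self):
        # B entirely inside a rigid cluster: no DOF to remove
        edges = [(0, 1, 6), (1, 2, 6), (2, 3, 5), (3, 4, 5)]
        net = make_network(5, edges)
        decomp = rigid_clusters(net)
        assert decomp.labels[0] == decomp.labels[1] == decomp.labels[2]
        res = rta_transmission(net,
                               SiteDefinition("a", np.array([3, 4])),
                               SiteDefinition("b", np.array([0, 1, 2])))
        assert res.dof_B_before == 0
        assert res.transmitted == 0


class TestScanProfile:
    def test_window_indexing_five_residues(self):
        # chain of 5 single-body "residues" -> windows {1..3},{2..4},{3..5}
        net = make_network(6, [(i, i + 1, 5) for i in range(5)])
        net.body_residues = [ResidueKey("X", i + 1) for i in range(6)]
        target = SiteDefinition("t", np.array([5]),
                                {ResidueKey("X", 6)})
        profile = rta_scan_profile(net, target, window=3)
        # residue 3 of the first five is covered by all three windows
        windows_per_residue = {1: 1, 2: 2, 3: 3, 4: 3, 5: 3, 6: 3}
        # (residue 6 is the target's residue; windows overlapping it skip)
        assert set(profile.intensity) == {ResidueKey("X", i + 1)
                                          for i in range(6)}

    def test_profile_nonzero_only_on_pathway(self):
        toy = gen_allosteric_toy(1, 4)
        profile = rta_scan_profile(toy.network, toy.site_b)
        severed_profile = rta_scan_profile(toy.severed, toy.site_b)
        assert max(profile.intensity.values()) > 0
        assert max(severed_profile.intensity.values()) == 0

    def test_no_hbond_network_constant_over_cutoffs(self):
        toy = gen_allosteric_toy(1, 3)
        p1 = rta_scan_profile(toy.network, toy.site_b, cutoffs=[0.0])
        p2 = rta_scan_profile(toy.network, toy.site_b,
                              cutoffs=[-0.5, -1.0, -1.5])
        assert p1.intensity == p2.intensity

    def test_removing_regulatory_bodies_never_increases_transmission(self):
        toy = gen_allosteric_toy(2, 4)
        res = rta_transmission(toy.network, toy.site_a, toy.site_b)
        # delete one loop's path bodies (a "regulatory ligand" stand-in)
        drop = [b for b in range(toy.network.n_bodies)
                if b not in set(toy.site_a.bodies)
                and b not in set(toy.site_b.bodies)][:4]
        pruned = remove_bodies(toy.network, drop)
        remap = [b for b in range(toy.network.n_bodies)
                 if b not in set(drop)]
        new_a = np.array([remap.index(b) for b in toy.site_a.bodies])
        new_b = np.array([remap.index(b) for b in toy.site_b.bodies])
        res2 = rta_transmission(pruned, SiteDefinition("a", new_a),
                                SiteDefinition("b", new_b))
        assert res2.transmitted <= res.transmitted


class TestAUC:
    def test_constant_curve(self):
        assert allosteric_auc([0.0, 0.3, 1.0],
                              [2.5, 2.5, 2.5]).value == pytest.approx(2.5)

    @pytest.mark.parametrize("n", [2, 5, 17, 101])
    def test_linear_curve_any_grid(self, n):
        x = np.linspace(0.0, 1.0, n)
        assert allosteric_auc(x, x).value == pytest.approx(0.5, abs=1e-12)

    def test_matches_independent_trapezoid(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            x = np.sort(rng.uniform(0, 10, n))
            while np.any(np.diff(x) <= 0):
                x = np.sort(rng.uniform(0, 10, n))
            y = rng.uniform(-3, 5, n)
            mine = allosteric_auc(x, y).value
            assert mine == pytest.approx(float(np.trapezoid(y, x)),
                                         abs=1e-12)

    def test_additive_over_subintervals(self, rng):
        x = np.sort(rng.uniform(0, 1, 21))
        x[0], x[-1] = 0.0, 1.0
        y = rng.uniform(0, 2, 21)
        total = allosteric_auc(x, y).value
        left = allosteric_auc(x[:11], y[:11]).value
        right = allosteric_auc(x[10:], y[10:]).value
        assert total == pytest.approx(left + right, abs=1e-12)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            allosteric_auc([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])


class TestHotspots:
    def _profile(self, intensities):
        keys = [ResidueKey("A", i + 1) for i in range(len(intensities))]
        return RTAProfile(
            intensity=dict(zip(keys, intensities)),
            persistence={k: 1.0 for k in keys},
            window=3, cutoffs=np.array([-0.5]), target_label="t",
        )

    def test_uniform_profile_empty(self):
        profile = self._profile([2.0] * 10)
        assert call_hotspots(profile) == set()

    def test_single_peak(self):
        values = [0.1] * 19 + [5.0]
        profile = self._profile(values)
        assert call_hotspots(profile) == {ResidueKey("A", 20)}

    def test_all_zero_warns_empty(self):
        profile = self._profile([0.0] * 5)
        with pytest.warns(UserWarning):
            assert call_hotspots(profile) == set()

    def test_exclusion_mask(self):
        values = [0.1] * 19 + [5.0]
        profile = self._profile(values)
        out = call_hotspots(profile, exclude={ResidueKey("A", 20)})
        assert ResidueKey("A", 20) not in out
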