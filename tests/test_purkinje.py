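"""Conduction-system tests: stochastic growth topology, graph
propagation against an all-pairs oracle, bundle-branch block, PMJ
coupling semantics and the Stewart-cable velocity mode."""

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall
import scipy.sparse as sp

from crtsim import config as cfg
from crtsim import geometry as G
from crtsim.purkinje import (BR_LBB, LV_MAIN_BRANCHES, RV_MAIN_BRANCHES,
                             PurkinjeTree, TreeActivation, apply_lbbb,
                             couple_pmjs, grow_tree, propagate_tree,
                             purkinje_cable_cv)
from conftest import SEED


def _line_tree(n=11, spacing=2.5, cv=2.5):
    """Straight unbranched cable tree, helper for arithmetic checks."""
    nodes = np.zeros((n, 3))
    nodes[:, 0] = np.arange(n) * spacing
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return PurkinjeTree(
        nodes=nodes, edges=edges,
        edge_blocked=np.zeros(n - 1, dtype=bool),
        branch_label=np.full(n - 1, BR_LBB, dtype=np.int8),
        pmj_nodes=np.array([n - 1]), pmj_myo_nodes=np.array([0]),
        cv=cv, his_node=0)


class TestGrowth:
    def test_deterministic_for_fixed_seed(self, tiny_heart):
        mesh, tree = tiny_heart
        from crtsim.purkinje import GrowthParams
        again = grow_tree(mesh, seed=SEED,
                          params=GrowthParams(pmj_density_per_mm2=0.12))
        assert np.array_equal(tree.nodes, again.nodes)
        assert np.array_equal(tree.edges, again.edges)
        assert np.array_equal(tree.pmj_myo_nodes, again.pmj_myo_nodes)

    def test_main_branch_counts(self, tiny_heart):
        _, tree = tiny_heart
        present = set(tree.branch_label)
        assert set(LV_MAIN_BRANCHES) <= present
        assert set(RV_MAIN_BRANCHES) <= present

    def test_pmj_count_on_default_desk_scale_heart(self, default_mesh):
        tree = grow_tree(default_mesh, seed=SEED)
        assert 200 <= len(tree.pmj_nodes) <= 400

    def test_pmjs_are_leaves_on_the_endocardium(self, tiny_heart):
        mesh, tree = tiny_heart
        deg = np.zeros(tree.n_nodes, dtype=int)
        for a, b in tree.edges:
            deg[a] += 1
            deg[b] += 1
        assert np.all(deg[tree.pmj_nodes] == 1)
        tags = mesh.surface_tags[tree.pmj_myo_nodes]
        assert np.all((tags == G.TAG_LV_ENDO) | (tags == G.TAG_RV_ENDO))
        # paired myocardial node coincides with the tree leaf position
        d = np.linalg.norm(tree.nodes[tree.pmj_nodes]
                           - mesh.node_coords[tree.pmj_myo_nodes], axis=1)
        assert d.max() <= mesh.edge_length

    def test_connected_from_his(self, tiny_heart):
        _, tree = tiny_heart
        act = propagate_tree(tree, [(tree.his_node, 0.0)]).activation_time
        assert np.isfinite(act).all()

    def test_excessive_density_rejected(self, tiny_heart):
        mesh, _ = tiny_heart
        from crtsim.purkinje import GrowthParams
        with pytest.raises(ValueError):
            grow_tree(mesh, seed=SEED,
                      params=GrowthParams(pmj_density_per_mm2=50.0))


class TestPropagation:
    def test_straight_cable_arithmetic(self):
        tree = _line_tree(n=11, spacing=2.5, cv=2.5)   # 25 mm cable
        act = propagate_tree(tree, [(0, 0.0)]).activation_time
        assert act[-1] == pytest.approx(10.0, abs=1e-9)

    def test_two_sources_elementwise_minimum(self):
        tree = _line_tree(n=11)
        a = propagate_tree(tree, [(0, 0.0)]).activation_time
        b = propagate_tree(tree, [(10, 3.0)]).activation_time
        both = propagate_tree(tree, [(0, 0.0), (10, 3.0)]).activation_time
        np.testing.assert_allclose(both, np.minimum(a, b), atol=1e-9)

    def test_random_tree_matches_floyd_warshall(self):
        rng = np.random.default_rng(5)
        n = 50
        nodes = rng.uniform(0, 30, (n, 3))
        # random spanning tree: connect node k to a random earlier node
        parents = np.array([rng.integers(0, k) for k in range(1, n)])
        edges = np.column_stack([parents, np.arange(1, n)])
        tree = PurkinjeTree(
            nodes=nodes, edges=edges,
            edge_blocked=np.zeros(n - 1, dtype=bool),
            branch_label=np.full(n - 1, BR_LBB, dtype=np.int8),
            pmj_nodes=np.array([n - 1]), pmj_myo_nodes=np.array([0]),
            cv=2.5, his_node=0)
        act = propagate_tree(tree, [(0, 0.0)]).activation_time
        w = tree.edge_lengths() / tree.cv
        A = sp.coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]],
                                         np.r_[edges[:, 1], edges[:, 0]])),
                          shape=(n, n))
        dist = floyd_warshall(A.toarray())
        np.testing.assert_allclose(act, dist[0], atol=1e-9)

    def test_empty_sources_all_unreached(self):
        tree = _line_tree()
        act = propagate_tree(tree, []).activation_time
        assert np.isinf(act).all()

    def test_blocking_never_speeds_activation(self, tiny_heart):
        _, tree = tiny_heart
        base = propagate_tree(tree, [(tree.his_node, 0.0)]).activation_time
        blocked = apply_lbbb(tree)
        after = propagate_tree(blocked,
                               [(blocked.his_node, 0.0)]).activation_time
        assert np.all(after >= base - 1e-12)


class TestLBBB:
    def test_blocks_exactly_two_proximal_left_bundle_elements(self,
                                                              tiny_heart):
        _, tree = tiny_heart
        blocked = apply_lbbb(tree)
        assert blocked.edge_blocked.sum() == 2
        assert np.all(tree.branch_label[blocked.edge_blocked] == BR_LBB)

    def test_his_no_longer_reaches_lv_pmjs(self, tiny_heart):
        mesh, tree = tiny_heart
        blocked = apply_lbbb(tree)
        act = propagate_tree(blocked,
                             [(blocked.his_node, 0.0)]).activation_time
        lv = mesh.surface_tags[tree.pmj_myo_nodes] == G.TAG_LV_ENDO
        assert np.isinf(act[tree.pmj_nodes[lv]]).all()

    def test_rv_times_unaffected(self, tiny_heart):
        mesh, tree = tiny_heart
        base = propagate_tree(tree, [(tree.his_node, 0.0)]).activation_time
        blocked = apply_lbbb(tree)
        after = propagate_tree(blocked,
                               [(blocked.his_node, 0.0)]).activation_time
        rv = mesh.surface_tags[tree.pmj_myo_nodes] == G.TAG_RV_ENDO
        np.testing.assert_allclose(after[tree.pmj_nodes[rv]],
                                   base[tree.pmj_nodes[rv]], atol=1e-9)

    def test_retrograde_source_stays_distal_to_the_block(self, tiny_heart):
        mesh, tree = tiny_heart
        blocked = apply_lbbb(tree)
        lv = mesh.surface_tags[tree.pmj_myo_nodes] == G.TAG_LV_ENDO
        src = int(tree.pmj_nodes[lv][0])
        act = propagate_tree(blocked, [(src, 0.0)]).activation_time
        # reaches other LV PMJs but never the His node or RV section
        assert np.isfinite(act[tree.pmj_nodes[lv]]).sum() > 1
        assert np.isinf(act[blocked.his_node])
        rv = mesh.surface_tags[tree.pmj_myo_nodes] == G.TAG_RV_ENDO
        assert np.isinf(act[tree.pmj_nodes[rv]]).all()

    def test_tree_without_left_bundle_rejected(self):
        tree = _line_tree()
        tree.branch_label[:] = 0  # HIS only
        with pytest.raises(ValueError):
            apply_lbbb(tree)


class TestPMJCoupling:
    def test_refractory_guard_blocks_anterograde(self):
        tree = _line_tree()
        ta = TreeActivation(np.full(tree.n_nodes, 30.0))
        myo = np.full(1, 10.0)           # myocardium already active
        events = couple_pmjs(ta, myo, tree, "ANTERO")
        assert events == []

    def test_zero_delay_anterograde_time(self):
        tree = _line_tree()
        tree.pmj_delay_antero = 0.0
        ta = TreeActivation(np.full(tree.n_nodes, 30.0))
        myo = np.full(1, np.inf)
        events = couple_pmjs(ta, myo, tree, "ANTERO")
        assert events == [(0, 30.0)]

    def test_retrograde_event_and_causality(self):
        tree = _line_tree()
        ta = TreeActivation(np.full(tree.n_nodes, np.inf))
        myo = np.full(1, 12.0)
        events = couple_pmjs(ta, myo, tree, "RETRO")
        assert events == [(10, 12.0 + tree.pmj_delay_retro)]
        # a round trip through the same PMJ cannot precede the origin
        t_tree = events[0][1]
        back = t_tree + tree.pmj_delay_antero
        assert back > myo[0]

    def test_unknown_direction_rejected(self):
        tree = _line_tree()
        with pytest.raises(ValueError):
            couple_pmjs(TreeActivation(np.zeros(11)), np.zeros(1), tree, "X")


def test_cable_velocity_at_calibrated_diffusivity():
    cv = purkinje_cable_cv(cfg.PURKINJE_CABLE_DIFFUSIVITY)
    assert cv == pytest.approx(2.5, rel=0.05)
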