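"""Synthetic-geometry contracts: slab and biventricular meshes, fibers,
transmural layers, LV segmentation and lead sites."""

import numpy as np
import pytest

from crtsim import geometry as G


class TestSlab:
    def test_calibration_slab_counts(self):
        mesh = G.build_slab((20, 20, 6), 0.4)
        assert mesh.n_elements == 50 * 50 * 15 == 37500
        assert mesh.n_nodes == 51 * 51 * 16 == 41616

    def test_single_voxel(self):
        mesh = G.build_slab((0.4, 0.4, 0.4), 0.4)
        assert mesh.n_elements == 1 and mesh.n_nodes == 8

    def test_uniform_fibers_and_celltype(self):
        mesh = G.build_slab((2, 2, 0.8), 0.4, fiber_axis=(0, 3, 0))
        assert np.allclose(mesh.fiber_dirs, [0, 1, 0])
        assert np.all(mesh.celltype == G.CELL_ENDO)

    @pytest.mark.parametrize("dims,edge", [((0, 2, 2), 0.4),
                                           ((2, 2, 2), -0.1),
                                           ((2, 2, 2), 0.3)])
    def test_bad_inputs_rejected(self, dims, edge):
        with pytest.raises(ValueError):
            G.build_slab(dims, edge)


class TestBiventricle:
    def test_default_mesh_is_a_closed_solid(self, default_mesh):
        # voxel complex of a ball (two blind cavities open at the base)
        assert G.euler_characteristic(default_mesh) == 1

    def test_septum_touches_both_endocardial_surfaces(self, default_mesh):
        m = default_mesh
        sep_nodes = np.unique(m.hex_elements[m.region == G.REGION_SEPTUM])
        tags = m.surface_tags[sep_nodes]
        assert (tags == G.TAG_LV_ENDO).any() and (tags == G.TAG_RV_ENDO).any()

    def test_edge_refinement_scales_node_count(self):
        base = dict(lv_semi_axes=(21.0, 21.0, 31.5), lv_wall=6.3,
                    rv_wall=4.8)
        n1 = G.build_biventricle(G.BiventricleParams(**base, edge_mm=0.8)
                                 ).n_nodes
        n2 = G.build_biventricle(G.BiventricleParams(**base, edge_mm=1.6)
                                 ).n_nodes
        assert 1 / 11 < n2 / n1 < 1 / 5.0     # ~1/8 for halved resolution

    def test_degenerate_walls_rejected(self):
        with pytest.raises(ValueError):
            G.build_biventricle(G.BiventricleParams(lv_wall=-1.0))
        with pytest.raises(ValueError):
            G.build_biventricle(G.BiventricleParams(lv_wall=3.0, rv_wall=4.0))
        with pytest.raises(ValueError):  # edge coarser than wall/3
            G.build_biventricle(G.BiventricleParams(edge_mm=2.0))


class TestLayers:
    def test_half_open_boundaries(self, default_mesh):
        m = default_mesh
        fr = G.DEFAULT_LAYER_FRACTIONS
        eps = 1e-12
        below = m.depth < fr[0] - eps
        at = np.abs(m.depth - fr[0]) <= eps
        mid = (m.depth >= fr[0]) & (m.depth < fr[0] + fr[1])
        assert np.all(m.celltype[below] == G.CELL_ENDO)
        assert np.all(m.celltype[at] == G.CELL_MID)   # lower-inclusive
        assert np.all(m.celltype[mid] == G.CELL_MID)
        assert np.all(m.celltype[m.depth >= fr[0] + fr[1]] == G.CELL_EPI)

    def test_septal_volume_fractions_recovered(self, default_mesh):
        # The septum is flat enough that volume fractions equal the
        # requested thickness fractions; on the thick curved LV free
        # wall, equal-thickness shells hold more volume epicardially,
        # so the whole-heart fractions are checked loosely.
        m = default_mesh
        sep = m.celltype[m.region == G.REGION_SEPTUM]
        frac = np.bincount(sep, minlength=3) / sep.size
        assert np.all(np.abs(frac - (0.17, 0.41, 0.42)) < 0.02)
        allfrac = np.bincount(m.celltype, minlength=3) / m.n_elements
        assert np.all(np.abs(allfrac - (0.17, 0.41, 0.42)) < 0.08)

    def test_bad_fractions_rejected(self, default_mesh):
        with pytest.raises(ValueError):
            G.assign_transmural_layers(default_mesh, (0.2, 0.2, 0.2))


class TestFibers:
    def test_unit_norm_and_helix_interpolation(self, default_mesh):
        m = default_mesh
        assert np.allclose(np.linalg.norm(m.fiber_dirs, axis=1), 1.0,
                           atol=1e-9)
        # recover the helix angle from the fiber and the local frame
        n = m.normals
        zhat = np.array([0.0, 0.0, 1.0])
        circ = np.cross(np.broadcast_to(zhat, n.shape), n)
        keep = np.linalg.norm(circ, axis=1) > 1e-6
        circ = circ[keep] / np.linalg.norm(circ[keep], axis=1, keepdims=True)
        longd = np.cross(n[keep], circ)
        f = m.fiber_dirs[keep]
        alpha = np.degrees(np.arctan2(np.sum(f * longd, axis=1),
                                      np.sum(f * circ, axis=1)))
        expected = 60.0 - 120.0 * m.depth[keep]
        assert np.percentile(np.abs(alpha - expected), 99) < 1.0

    def test_transmural_continuity(self, default_mesh):
        # helix angle is linear in depth, so its change between
        # transmurally adjacent elements is bounded by the gradient step
        m = default_mesh
        bound = 120.0 * m.edge_length / 4.0 + 1.0   # RV wall is thinnest
        a = 60.0 - 120.0 * m.depth
        vox = {tuple(v): i for i, v in enumerate(map(tuple, m.voxel_ijk))}
        ii = m.voxel_ijk
        jumps = []
        for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            for i, v in enumerate(m.voxel_ijk[:2000]):
                nb = vox.get((v[0] + di, v[1] + dj, v[2] + dk))
                if nb is not None and m.region[i] == m.region[nb]:
                    jumps.append(abs(a[i] - a[nb]))
        assert np.percentile(jumps, 99) < bound

    def test_slab_has_no_depth_field(self):
        slab = G.build_slab((2, 2, 0.8), 0.4)
        with pytest.raises(ValueError):
            G.assign_fibers_streeter(slab)
        with pytest.raises(ValueError):
            G.assign_transmural_layers(slab)


class TestSegmentsAndLeads:
    def test_nine_nonempty_segments_partition_free_wall(self, default_mesh):
        m = default_mesh
        seg_codes = [c for c in np.unique(m.region) if 1 <= c <= 9]
        assert len(seg_codes) == 9
        assert not (m.region == G.REGION_LV_FREEWALL).any()

    def test_segmentation_requires_free_wall(self):
        slab = G.build_slab((2, 2, 0.8), 0.4)
        with pytest.raises(ValueError):
            G.segment_lv_free_wall(slab)

    def test_lead_label_enumeration(self):
        labels = G.all_lead_labels()
        assert len(labels) == 3 + 18 == 21
        assert len(set(labels)) == 21

    def test_all_leads_placeable(self, default_mesh):
        sites = [G.place_lead(default_mesh, lab)
                 for lab in G.all_lead_labels()]
        assert len(sites) == 21
        for s in sites:
            assert s.node_set.size >= 1

    def test_rv_apex_on_rv_septal_endocardium(self, default_mesh):
        m = default_mesh
        site = G.place_lead(m, "RV_APEX")
        assert np.all(m.surface_tags[site.node_set] == G.TAG_RV_ENDO)
        rv_endo_z = m.node_coords[m.surface_tags == G.TAG_RV_ENDO][:, 2]
        assert site.center[2] < np.percentile(rv_endo_z, 20)

    def test_epi_and_endo_sites_disjoint(self, default_mesh):
        a = G.place_lead(default_mesh, "LV_POSTERIOR_MID_ENDO")
        b = G.place_lead(default_mesh, "LV_POSTERIOR_MID_EPI")
        assert not set(a.node_set) & set(b.node_set)

    def test_unknown_label_rejected(self, default_mesh):
        with pytest.raises(ValueError):
            G.place_lead(default_mesh, "LV_SEPTAL_MID_ENDO")


def test_mesh_determinism():
    p = G.BiventricleParams().scaled(0.35, 0.8)
    a = G.build_biventricle(p)
    b = G.build_biventricle(p)
    assert np.array_equal(a.node_coords, b.node_coords)
    assert np.array_equal(a.hex_elements, b.hex_elements)
    assert np.array_equal(a.region, b.region)
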