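"""Monodomain solver tests: operator structure, conservation,
activation semantics, CV measurement, HF scaling and convergence."""

import numpy as np
import pytest

from crtsim import config as cfg
from crtsim.cells import IonicModelParams
from crtsim.geometry import build_slab
from crtsim.monodomain import (ConductivityField, StimulusSpec,
                               apply_hf, assemble_diffusion,
                               lumped_volume_fractions, measure_cv,
                               run_simulation, slab_cv, SimulationResult)


@pytest.fixture(scope="module")
def small_slab():
    return build_slab((4, 4, 1.6), 0.4)


class TestOperator:
    def test_annihilates_constants(self, small_slab):
        L = assemble_diffusion(small_slab, ConductivityField())
        v = np.full(small_slab.n_nodes, 3.7)
        assert np.abs(L @ v).max() < 1e-10

    def test_symmetric_with_zero_row_sums(self, small_slab):
        L = assemble_diffusion(small_slab, ConductivityField())
        assert abs(L - L.T).max() < 1e-12
        assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-12

    def test_isotropic_interior_stencil_is_seven_point(self, small_slab):
        iso = ConductivityField(sigma_l=0.5, sigma_t=0.5,
                                transverse_correction=1.0)
        L = assemble_diffusion(small_slab, iso)
        D = 0.5 * iso.diffusivity_scale
        h = small_slab.edge_length
        coords = small_slab.node_coords
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        interior = np.all((coords > lo + h - 1e-9)
                          & (coords < hi - h + 1e-9), axis=1)
        n = int(np.where(interior)[0][0])
        row = L.getrow(n).toarray().ravel()
        assert row[n] == pytest.approx(-6 * D / h ** 2)
        off = np.sort(row[row != 0])
        assert off.size == 7
        assert np.allclose(off[1:], D / h ** 2)

    def test_anisotropy_direction_ratio(self, small_slab):
        """A quadratic field along the fibers feels sigma_L; the same
        field across them feels sigma_T (correction disabled)."""
        cond = ConductivityField(transverse_correction=1.0)
        L = assemble_diffusion(small_slab, cond)
        x, y = small_slab.node_coords[:, 0], small_slab.node_coords[:, 1]
        coords = small_slab.node_coords
        h = small_slab.edge_length
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        interior = np.all((coords > lo + h - 1e-9)
                          & (coords < hi - h + 1e-9), axis=1)
        rx = (L @ (x ** 2))[interior]
        ry = (L @ (y ** 2))[interior]
        assert np.median(rx / ry) == pytest.approx(
            cond.sigma_l / cond.sigma_t, rel=1e-9)

    def test_non_spd_tensor_rejected(self, small_slab):
        with pytest.raises(ValueError):
            ConductivityField(sigma_l=0.1, sigma_t=0.5)

    def test_discrete_conservation_of_diffusion(self, small_slab):
        """Pure diffusion preserves the mesh-integrated potential."""
        import scipy.sparse as sp
        L = assemble_diffusion(small_slab, ConductivityField())
        m = lumped_volume_fractions(small_slab)
        Ls = sp.diags(1.0 / m) @ L
        rng = np.random.default_rng(0)
        v = rng.normal(size=small_slab.n_nodes)
        total0 = float(m @ v)
        for _ in range(500):
            v = v + 0.02 * (Ls @ v)
        assert float(m @ v) == pytest.approx(total0, rel=1e-8)


class TestSimulation:
    def test_no_stimulus_no_activation(self, small_slab):
        r = run_simulation(small_slab, ConductivityField(),
                           IonicModelParams.ord_modified("ENDO"), [],
                           duration=5.0, record_vm=False)
        assert np.isinf(r.activation_time).all()

    def test_subthreshold_depolarisation_not_marked_active(self, small_slab):
        """Nodes pushed well above rest but below -10 mV never count as
        activated."""
        nodes = np.arange(small_slab.n_nodes)
        stim = StimulusSpec(node_set=nodes, amplitude=10.0, start=0.0,
                            duration=2.0)
        r = run_simulation(small_slab, ConductivityField(),
                           IonicModelParams.ord_modified("ENDO"), [stim],
                           duration=4.0, record_vm=True, sample_dt=0.5)
        vmax = r.V_m_samples.max()
        assert -70 < vmax < -10.0
        assert np.isinf(r.activation_time).all()

    def test_unstable_dt_rejected(self, small_slab):
        with pytest.raises(ValueError, match="unstable"):
            run_simulation(small_slab, ConductivityField(),
                           IonicModelParams.ord_modified("ENDO"), [],
                           duration=1.0, dt=5.0)

    def test_bad_stimulus_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(node_set=np.array([0]), amplitude=-5.0, start=0.0)
        with pytest.raises(ValueError):
            StimulusSpec(node_set=np.array([], dtype=int), amplitude=5.0,
                         start=0.0)


class TestMeasureCV:
    def _fake_result(self, mesh, act):
        return SimulationResult(times=np.array([0.0]), V_m_samples=None,
                                activation_time=act, stimuli_log=[],
                                dt=0.02, duration=1.0)

    def test_synthetic_linear_map(self):
        mesh = build_slab((20, 2, 0.8), 0.4)
        act = mesh.node_coords[:, 0] / 2.0        # t = x/2 -> 2 mm/ms
        r = self._fake_result(mesh, act)
        a = int(np.argmin(np.linalg.norm(mesh.node_coords
                                         - np.array([4, 1, 0.4]), axis=1)))
        b = int(np.argmin(np.linalg.norm(mesh.node_coords
                                         - np.array([16, 1, 0.4]), axis=1)))
        assert measure_cv(r, mesh, a, b) == pytest.approx(2.0)

    def test_unactivated_probe_named(self):
        mesh = build_slab((20, 2, 0.8), 0.4)
        act = np.full(mesh.n_nodes, np.inf)
        act[0] = 1.0
        r = self._fake_result(mesh, act)
        with pytest.raises(ValueError, match="probe_b"):
            measure_cv(r, mesh, 0, 10)

    def test_probe_separation_enforced(self):
        mesh = build_slab((20, 2, 0.8), 0.4)
        act = mesh.node_coords[:, 0]
        r = self._fake_result(mesh, act)
        mid = np.array([10, 1, 0.4])
        a = int(np.argmin(np.linalg.norm(mesh.node_coords - mid, axis=1)))
        with pytest.raises(ValueError, match="too close"):
            measure_cv(r, mesh, a, a + 1)


class TestHeartFailure:
    def test_multiplier_is_the_calibrated_exponent_law(self):
        hf = apply_hf(ConductivityField(), 0.5)
        assert hf.hf_scale == pytest.approx(0.5 ** cfg.HF_SCALE_EXPONENT)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_reduction_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_hf(ConductivityField(), bad)


@pytest.fixture(scope="module")
def convergence_cvs():
    return {
        "base": slab_cv("L", in_plane_mm=12.0),
        "dt_half": slab_cv("L", in_plane_mm=12.0, dt=0.01),
        "thick": slab_cv("L", in_plane_mm=12.0, thickness_mm=2.0),
        "fine": slab_cv("L", in_plane_mm=12.0, edge_mm=0.2, dt=0.01),
    }


class TestConvergence:
    """Slab CV sensitivity to dt, thickness and mesh size.

    Runs on a 12 mm plate (probe spacing still >= 10 edges).  The h
    refinement bound reflects the measured behaviour of the 7-point
    scheme at the calibrated diffusivity: the 0.4 mm working grid sits
    about 13% below its fine-grid limit, which is precisely why the CV
    calibration is performed at the working resolution.
    """

    def test_dt_halving_changes_cv_below_two_percent(self, convergence_cvs):
        c = convergence_cvs
        assert abs(c["dt_half"] / c["base"] - 1.0) < 0.02

    def test_planar_cv_thickness_invariant(self, convergence_cvs):
        c = convergence_cvs
        assert abs(c["thick"] / c["base"] - 1.0) < 0.03

    def test_h_refinement_within_measured_band(self, convergence_cvs):
        c = convergence_cvs
        assert abs(c["fine"] / c["dt_half"] - 1.0) < 0.16


def test_anisotropy_ratio_matches_sqrt_conductivity(slab_cvs):
    """CV_L / CV_T is within 10% of sqrt(sigma_L / sigma_T)."""
    ratio = slab_cvs["L"] / slab_cvs["T"]
    assert ratio == pytest.approx(np.sqrt(0.5 / 0.1), rel=0.10)
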