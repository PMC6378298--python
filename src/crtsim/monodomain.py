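"""Monodomain reaction-diffusion solver on structured hexahedral meshes.

The transmembrane potential obeys

    dV/dt = div(D grad V) - I_ion + I_stim

per unit capacitance, with D the anisotropic effective diffusivity built
from the fiber field (D = s * [sigma_T I + (sigma_L - sigma_T) f f^T],
s the calibrated diffusivity scale) and zero-flux boundaries.

Spatial discretisation is finite differences on the voxel grid with
node-centred unknowns: the diagonal tensor entries use the conservative
7-point (edge-conductance) stencil; fiber-rotation cross terms are added
through trilinear-element cross-stiffness contributions.  Time stepping
is operator splitting: explicit diffusion plus the Rush-Larsen/Euler
membrane update of the cell models.  Activation is the first upward
crossing of -10 mV, checked at every internal step.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import config as _cfg
from .cells import IonicModelParams, ord_initial_state
from .cells.ord import ord_step
from .geometry import Mesh

ACTIVATION_THRESHOLD_MV = -10.0

# element-corner pairs forming the 4 edges parallel to each axis
_EDGE_PAIRS = {
    0: ((0, 1), (3, 2), (4, 5), (7, 6)),
    1: ((0, 3), (1, 2), (4, 7), (5, 6)),
    2: ((0, 4), (1, 5), (2, 6), (3, 7)),
}


@dataclass
class ConductivityField:
    """Anisotropic conductivity with the heart-failure scaling knob.

    ``hf_scale`` multiplies the diffusivity tensor; because conduction
    velocity scales with the square root of the diffusivity, halving CV
    requires hf_scale = 0.25.
    """

    sigma_l: float = _cfg.SIGMA_L
    sigma_t: float = _cfg.SIGMA_T
    hf_scale: float = 1.0
    diffusivity_scale: float = _cfg.DIFFUSIVITY_SCALE
    transverse_correction: float = _cfg.TRANSVERSE_CORRECTION

    def __post_init__(self):
        if not (self.sigma_l >= self.sigma_t > 0):
            raise ValueError("need sigma_l >= sigma_t > 0")
        if self.hf_scale <= 0 or self.diffusivity_scale <= 0 \
                or self.transverse_correction <= 0:
            raise ValueError("scales must be positive")

    def tensors(self, mesh: Mesh) -> np.ndarray:
        """(E, 3, 3) effective diffusivity tensors in mm^2/ms.

        The transverse diffusivity carries the calibrated grid
        correction (the coarse grid under-resolves the narrow
        cross-fiber wavefront; see config).
        """
        f = mesh.fiber_dirs
        s = self.diffusivity_scale * self.hf_scale
        st = self.sigma_t * self.transverse_correction
        eye = np.eye(3)[None, :, :]
        D = s * (st * eye
                 + (self.sigma_l - st) * f[:, :, None] * f[:, None, :])
        return D


def apply_hf(cond: ConductivityField,
             cv_reduction: float = _cfg.HF_CV_REDUCTION) -> ConductivityField:
    """Heart-failure remodelling: reduce CV by the given fraction.

    In the continuum, CV scales as sqrt(diffusivity), so the multiplier
    would be (1 - cv_reduction)^2; on the working 0.4 mm grid the
    narrower slowed wavefront loses extra speed to discretisation, so
    the exponent is calibrated (see config.HF_SCALE_EXPONENT) such that
    the *measured* slab CV falls by exactly ``cv_reduction``.
    """
    if not 0.0 < cv_reduction < 1.0:
        raise ValueError("cv_reduction must lie strictly between 0 and 1")
    mult = (1.0 - cv_reduction) ** _cfg.HF_SCALE_EXPONENT
    return ConductivityField(sigma_l=cond.sigma_l, sigma_t=cond.sigma_t,
                             hf_scale=cond.hf_scale * mult,
                             diffusivity_scale=cond.diffusivity_scale,
                             transverse_correction=cond.transverse_correction)


@dataclass(frozen=True)
class StimulusSpec:
    """Transmembrane current injection on a node set."""

    node_set: np.ndarray
    amplitude: float            # uA/uF, depolarising
    start: float                # ms
    duration: float = 2.0       # ms

    def __post_init__(self):
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("stimulus amplitude and duration must be positive")
        if len(np.atleast_1d(self.node_set)) == 0:
            raise ValueError("stimulus node_set is empty")


#: per-node current below which a focal stimulus fails to launch a wave
#: on coarse grids (source-sink mismatch); measured on the test hearts
STIM_LAUNCH_FLOOR = 100.0


def stimulus_cluster(mesh: Mesh, node_set, amplitude: float,
                     cube_volume_mm3: float = 0.5):
    """Resolution-aware focal stimulus: (nodes, per-node amplitude).

    The electrode occupies ``cube_volume_mm3``; on grids finer than the
    cube the given node set is kept and the nominal per-node amplitude
    applies.  On coarser grids the set is expanded to the nodes within
    one grid spacing of the site so a wave can launch (a single coarse
    node cannot drive its neighbours), and the per-node amplitude is the
    charge-conserving value, clipped to [STIM_LAUNCH_FLOOR, amplitude].
    """
    node_set = np.atleast_1d(np.asarray(node_set, dtype=np.int64))
    h = mesh.edge_length
    radius = 1.05 * max((cube_volume_mm3 ** (1.0 / 3.0)) / 2.0, h)
    center = mesh.node_coords[node_set].mean(axis=0)
    d = np.linalg.norm(mesh.node_coords - center[None, :], axis=1)
    nodes = np.unique(np.concatenate([node_set, np.where(d <= radius)[0]]))
    amp = amplitude * cube_volume_mm3 / (nodes.size * h ** 3)
    amp = float(np.clip(amp, min(STIM_LAUNCH_FLOOR, amplitude), amplitude))
    return nodes, amp


@dataclass
class SimulationResult:
    times: np.ndarray                 # sample instants, ms
    V_m_samples: Optional[np.ndarray]  # (n_samples, N) float32 or None
    activation_time: np.ndarray       # (N,) ms, inf when never activated
    stimuli_log: list
    dt: float
    duration: float
    tree_activation: Optional[np.ndarray] = None   # per tree node, ms


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

# trilinear shape-function gradients at the 2x2x2 Gauss points of the
# reference cube [0,1]^3 (unit edge; scale by 1/h afterwards)
def _gauss_gradients():
    g = 0.5 - 0.5 / np.sqrt(3.0)
    pts = [(a, b, c) for a in (g, 1 - g) for b in (g, 1 - g) for c in (g, 1 - g)]
    corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
               (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    G = np.empty((8, 3, 8))
    for gp, (x, y, z) in enumerate(pts):
        for ci, (cx, cy, cz) in enumerate(corners):
            sx = x if cx else 1 - x
            sy = y if cy else 1 - y
            sz = z if cz else 1 - z
            dx = (1.0 if cx else -1.0) * sy * sz
            dy = (1.0 if cy else -1.0) * sx * sz
            dz = (1.0 if cz else -1.0) * sx * sy
            G[gp, :, ci] = (dx, dy, dz)
    return G


_GAUSS_G = _gauss_gradients()


def assemble_diffusion(mesh: Mesh, cond: ConductivityField) -> sp.csr_matrix:
    """Sparse operator L with L v ~= div(D grad v), zero-flux boundaries.

    Symmetric with zero row sums (discrete conservation).  With an
    isotropic tensor on a full rectangular grid the interior stencil is
    exactly the 7-point Laplacian D / h^2.
    """
    D = cond.tensors(mesh)
    ev = np.linalg.eigvalsh(D)
    if np.any(ev <= 0):
        raise ValueError("element diffusivity tensor is not positive definite")
    h = mesh.edge_length
    E = mesh.n_elements
    N = mesh.n_nodes
    elems = mesh.hex_elements

    rows = []
    cols = []
    vals = []

    def _add(i, j, w):
        rows.append(i)
        cols.append(j)
        vals.append(w)

    # axis terms: edge conductances, sum over adjacent elements / 4
    for axis in range(3):
        w_e = D[:, axis, axis] / (4.0 * h * h)
        for (a, b) in _EDGE_PAIRS[axis]:
            na, nb = elems[:, a], elems[:, b]
            _add(na, nb, w_e)
            _add(nb, na, w_e)
            _add(na, na, -w_e)
            _add(nb, nb, -w_e)

    # cross terms: trilinear-element stiffness difference (full - diagonal)
    Dcross = D.copy()
    Dcross[:, np.arange(3), np.arange(3)] = 0.0
    if np.abs(Dcross).max() > 1e-15:
        # K_e = sum_g (h^3/8) (G/h)^T D (G/h);  L_cross = -K_e / h^3
        K = np.einsum("gai,eab,gbj->eij", _GAUSS_G, Dcross, _GAUSS_G) / 8.0
        K /= h * h
        ii = np.repeat(elems[:, :, None], 8, axis=2)
        jj = np.repeat(elems[:, None, :], 8, axis=1)
        rows.append(ii.ravel())
        cols.append(jj.ravel())
        vals.append(-K.ravel())

    rows = np.concatenate([np.asarray(r).ravel() for r in rows])
    cols = np.concatenate([np.asarray(c).ravel() for c in cols])
    vals = np.concatenate([np.asarray(v).ravel() for v in vals])
    L = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    L.sum_duplicates()
    return L


def lumped_volume_fractions(mesh: Mesh) -> np.ndarray:
    """Per-node dual-cell volume as a fraction of h^3.

    1 for interior nodes, 1/2 on faces, 1/4 on edges, 1/8 at corners.
    The solver divides the flux divergence by these so that boundary
    nodes see the same flux-per-volume as interior ones (a planar wave
    then stays exactly planar and CV is thickness-invariant).
    """
    frac = np.zeros(mesh.n_nodes)
    np.add.at(frac, mesh.hex_elements.ravel(), 1.0 / 8.0)
    return frac


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


def _node_celltype(mesh: Mesh) -> np.ndarray:
    """Per-node cell type: taken from the lowest-index containing element."""
    ct = np.full(mesh.n_nodes, -1, dtype=np.int64)
    # iterate elements in reverse so the lowest element index wins
    for corner in range(8):
        ct[mesh.hex_elements[::-1, corner]] = mesh.celltype[::-1]
    return ct


def run_simulation(mesh: Mesh, cond: ConductivityField,
                   params: IonicModelParams,
                   stimuli: Sequence[StimulusSpec],
                   tree=None,
                   tree_sources: Sequence[tuple] = (),
                   duration: float = 100.0,
                   dt: float = 0.02,
                   sample_dt: float = 1.0,
                   record_vm: bool = True,
                   activation_threshold: float = ACTIVATION_THRESHOLD_MV,
                   early_stop_nodes: Optional[np.ndarray] = None,
                   stop_after_full_activation_ms: Optional[float] = None,
                   pmj_stim_amplitude: float = 400.0,
                   pmj_stim_duration: float = 2.0,
                   initial_state: Optional[np.ndarray] = None,
                   ) -> SimulationResult:
    """Integrate the coupled tissue (+ optional Purkinje tree) system.

    ``stimuli`` act on myocardial nodes; ``tree_sources`` are
    (tree_node, onset_ms) events fed to the conduction tree (e.g. a His
    stimulus).  Anterograde PMJ events become myocardial stimuli of
    ``pmj_stim_amplitude`` after the tree's anterograde junction delay;
    myocardial activation of a PMJ-paired node feeds back retrogradely.

    Early-exit options: ``early_stop_nodes`` stops 2 ms after all listed
    nodes have activated; ``stop_after_full_activation_ms`` stops the
    given number of ms after every myocardial node has activated (enough
    tail for QRS-end delineation).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.model_id not in ("ORD_MODIFIED", "ORD_ORIGINAL"):
        raise ValueError("tissue simulation uses the ventricular models")

    L = assemble_diffusion(mesh, cond)
    # divide fluxes by the lumped dual volumes (see lumped_volume_fractions)
    mvol = lumped_volume_fractions(mesh)
    L = sp.diags(1.0 / mvol) @ L
    # explicit-diffusion stability bound (Gershgorin)
    diag = np.abs(L.diagonal()).max()
    if diag > 0 and dt > 2.0 / diag:
        raise ValueError(f"dt={dt} ms unstable for this operator; "
                         f"need dt <= {2.0 / diag:.4f} ms")

    N = mesh.n_nodes
    s0 = ord_initial_state() if initial_state is None else \
        np.asarray(initial_state, dtype=float)
    S = np.tile(s0, (N, 1))
    ct = _node_celltype(mesh)
    mss, hjss, tauhj = params.gate_mod_flags

    n_steps = int(round(duration / dt))
    sample_every = max(int(round(sample_dt / dt)), 1)
    act = np.full(N, np.inf)
    istim = np.zeros(N)

    times = []
    samples = [] if record_vm else None

    # --- Purkinje bookkeeping ---------------------------------------------
    pmj_events = []        # heap of (fire_time, myo_node, pmj_index)
    tree_act = None
    retro_buffer = []
    if tree is not None:
        from .purkinje import propagate_tree
        sources = list(tree_sources)
        if sources:
            tree_act = propagate_tree(tree, sources).activation_time
        else:
            tree_act = np.full(tree.n_nodes, np.inf)
        for k, (tn, mn) in enumerate(zip(tree.pmj_nodes, tree.pmj_myo_nodes)):
            if np.isfinite(tree_act[tn]):
                heapq.heappush(pmj_events,
                               (tree_act[tn] + tree.pmj_delay_antero, mn, k))
    elif tree_sources:
        raise ValueError("tree_sources given without a tree")

    stim_list = [(np.asarray(st.node_set, dtype=np.int64), st.amplitude,
                  st.start, st.start + st.duration) for st in stimuli]
    active_pmj_stims = []   # (nodes, amp, until_time)
    pmj_clusters = {}
    if tree is not None:
        for k, mn in enumerate(tree.pmj_myo_nodes):
            pmj_clusters[k] = stimulus_cluster(mesh, [mn],
                                               pmj_stim_amplitude)

    stop_at = None
    t = 0.0
    V = S[:, 0]
    if record_vm:
        times.append(0.0)
        samples.append(V.astype(np.float32).copy())

    step = 0
    while step < n_steps:
        t = step * dt
        # assemble stimulus for this step
        istim[:] = 0.0
        for nodes, amp, t0, t1 in stim_list:
            if t0 <= t < t1:
                istim[nodes] += amp
        # PMJ anterograde events: activate unless myocardium got there first
        while pmj_events and pmj_events[0][0] <= t:
            ft, mn, k = heapq.heappop(pmj_events)
            if not np.isfinite(act[mn]):
                nodes_k, amp_k = pmj_clusters[k]
                active_pmj_stims.append((nodes_k, amp_k,
                                         ft + pmj_stim_duration))
        if active_pmj_stims:
            active_pmj_stims = [s for s in active_pmj_stims if s[2] > t]
            # overlapping junction clusters saturate rather than add
            for nodes_k, amp_k, _ in active_pmj_stims:
                istim[nodes_k] = np.maximum(istim[nodes_k], amp_k)

        # injection into depolarised tissue is physiologically ineffective
        # and numerically destabilising on coarse grids: gate it off
        if active_pmj_stims or stim_list:
            istim[V > 0.0] = 0.0

        # operator-split step: explicit diffusion, then membrane kinetics
        V += dt * (L @ V)
        ord_step(S, ct, istim, dt, mss, hjss, tauhj, params.G_Na, params.G_NaL)

        step += 1
        t = step * dt

        newly = np.isinf(act) & (V >= activation_threshold)
        if newly.any():
            act[newly] = t
            if tree is not None:
                hit = newly[tree.pmj_myo_nodes]
                if hit.any():
                    for k in np.where(hit)[0]:
                        retro_buffer.append(
                            (int(tree.pmj_nodes[k]),
                             t + tree.pmj_delay_retro))

        # fold retrograde entries back into the tree (batched per step)
        if retro_buffer and tree is not None:
            from .purkinje import propagate_tree
            upd = propagate_tree(tree, retro_buffer,
                                 initial=tree_act).activation_time
            improved = upd < tree_act - 1e-12
            tree_act = np.minimum(tree_act, upd)
            retro_buffer = []
            if improved.any():
                for k, (tn, mn) in enumerate(zip(tree.pmj_nodes,
                                                 tree.pmj_myo_nodes)):
                    if improved[tn] and not np.isfinite(act[mn]):
                        heapq.heappush(
                            pmj_events,
                            (tree_act[tn] + tree.pmj_delay_antero, mn, k))

        if np.abs(V).max() > 200.0:
            raise RuntimeError(f"monodomain instability at t={t:.3f} ms "
                               f"(step {step}): |V| exceeded 200 mV")

        if record_vm and step % sample_every == 0:
            times.append(t)
            samples.append(V.astype(np.float32).copy())

        # early-exit logic
        if stop_at is None:
            if early_stop_nodes is not None and \
                    np.all(np.isfinite(act[early_stop_nodes])):
                stop_at = t + 2.0
            elif stop_after_full_activation_ms is not None and \
                    not np.isinf(act).any():
                stop_at = t + stop_after_full_activation_ms
        if stop_at is not None and t >= stop_at:
            break

    return SimulationResult(
        times=np.asarray(times),
        V_m_samples=np.asarray(samples) if record_vm else None,
        activation_time=act,
        stimuli_log=list(stimuli),
        dt=dt,
        duration=t,
        tree_activation=tree_act,
    )


# ---------------------------------------------------------------------------
# conduction-velocity measurement
# ---------------------------------------------------------------------------


def measure_cv(result: SimulationResult, mesh: Mesh,
               probe_a: int, probe_b: int,
               min_edge_separation: int = 10,
               boundary_margin_edges: int = 5) -> float:
    """Conduction velocity (m/s) between two activated probes.

    Probes must be separated by at least ``min_edge_separation`` edge
    lengths along the dominant measurement axis and sit at least
    ``boundary_margin_edges`` from the domain boundary along that axis.
    mm/ms equals m/s, so no unit conversion is needed.
    """
    ta, tb = result.activation_time[probe_a], result.activation_time[probe_b]
    for name, tval in (("probe_a", ta), ("probe_b", tb)):
        if not np.isfinite(tval):
            raise ValueError(f"{name} never activated")
    pa, pb = mesh.node_coords[probe_a], mesh.node_coords[probe_b]
    delta = pb - pa
    axis = int(np.argmax(np.abs(delta)))
    h = mesh.edge_length
    if abs(delta[axis]) < min_edge_separation * h - 1e-9:
        raise ValueError("probes too close for a reliable CV estimate")
    lo = mesh.node_coords[:, axis].min()
    hi = mesh.node_coords[:, axis].max()
    margin = boundary_margin_edges * h
    for name, p in (("probe_a", pa), ("probe_b", pb)):
        if p[axis] < lo + margin - 1e-9 or p[axis] > hi - margin + 1e-9:
            raise ValueError(f"{name} too close to the domain boundary")
    if tb == ta:
        raise ValueError("probes activated simultaneously")
    cv = float(np.linalg.norm(delta) / abs(tb - ta))
    return cv


def slab_cv(direction: str = "L",
            cond: Optional[ConductivityField] = None,
            params: Optional[IonicModelParams] = None,
            in_plane_mm: float = 20.0,
            thickness_mm: float = 0.8,
            edge_mm: float = 0.4,
            dt: float = 0.02,
            stim_amplitude: float = 100.0,
            stim_duration: float = 1.0) -> float:
    """Planar-wavefront CV on the calibration slab.

    ``direction`` 'L' paces a fiber-perpendicular face and measures along
    the fibers (x); 'T' paces a fiber-parallel face and measures across
    them (y).  Fibers run along +x.  The slab is ``in_plane_mm`` square
    and ``thickness_mm`` thick (planar CV is thickness-invariant).
    """
    from .geometry import build_slab

    if direction not in ("L", "T"):
        raise ValueError("direction must be 'L' or 'T'")
    cond = cond or ConductivityField()
    params = params or IonicModelParams.ord_modified("ENDO")
    mesh = build_slab((in_plane_mm, in_plane_mm, thickness_mm), edge_mm,
                      fiber_axis=(1.0, 0.0, 0.0))
    axis = 0 if direction == "L" else 1
    coords = mesh.node_coords
    face = coords[:, axis] <= edge_mm * 1.01   # two node layers
    # a plane-wave stimulus has no lateral diffusion sink, so it uses a
    # gentler pulse than the 400 uA/uF lead cubes
    stim = StimulusSpec(node_set=np.where(face)[0], amplitude=stim_amplitude,
                        start=0.0, duration=stim_duration)

    span = in_plane_mm
    mid = in_plane_mm / 2.0
    zmid = thickness_mm / 2.0

    def _probe(frac):
        target = np.array([frac * span if axis == 0 else mid,
                           frac * span if axis == 1 else mid,
                           zmid])
        return int(np.argmin(np.linalg.norm(coords - target, axis=1)))

    pa, pb = _probe(0.30), _probe(0.70)
    # generous duration; early exit once the far probe activates
    result = run_simulation(mesh, cond, params, [stim], duration=160.0,
                            dt=dt, record_vm=False,
                            early_stop_nodes=np.array([pa, pb]))
    return measure_cv(result, mesh, pa, pb)
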