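"""Cardiac conduction system: stochastic Purkinje tree on the endocardial
surfaces, graph conduction, PMJ coupling and bundle-branch lesioning.

The tree is grown on the endocardial surface-node graph of the
biventricular mesh: a His stem bifurcates into left and right bundle
branches; the right bundle spawns 2 main branches (septal, descending to
the apex, and anterior, toward the moderator-band region) and the left
bundle 3 (posterior, septal/apical, anterior), following geodesic
corridors of the surface graph; randomly sampled endocardial sites become
Purkinje-myocardial junctions (PMJs), attached through their geodesic
paths, which produces the stochastic subdivision of each main branch.

Conduction through the tree is graph shortest-path at a constant
velocity (2.5 m/s after calibration); a Stewart-model 1D cable mode
exists for the velocity calibration itself.  Left bundle branch block is
modelled by zeroing the conductivity of the two proximal left-bundle
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from . import config as _cfg
from .geometry import (Mesh, TAG_LV_ENDO, TAG_RV_ENDO, REGION_SEPTUM)

# branch label codes
BR_HIS, BR_LBB, BR_RBB = 0, 1, 2
BR_LV_POST, BR_LV_SEPT, BR_LV_ANT = 3, 4, 5
BR_RV_SEPT, BR_RV_ANT = 6, 7
BR_TERMINAL = 8
BRANCH_NAMES = {BR_HIS: "HIS", BR_LBB: "LBB", BR_RBB: "RBB",
                BR_LV_POST: "LV_POST", BR_LV_SEPT: "LV_SEPT",
                BR_LV_ANT: "LV_ANT", BR_RV_SEPT: "RV_SEPT",
                BR_RV_ANT: "RV_ANT", BR_TERMINAL: "TERMINAL"}

LV_MAIN_BRANCHES = (BR_LV_POST, BR_LV_SEPT, BR_LV_ANT)
RV_MAIN_BRANCHES = (BR_RV_SEPT, BR_RV_ANT)


@dataclass
class PurkinjeTree:
    """Conduction-system graph; node 0 is the His entry."""

    nodes: np.ndarray              # (M, 3) mm
    edges: np.ndarray              # (K, 2) int
    edge_blocked: np.ndarray       # (K,) bool
    branch_label: np.ndarray       # (K,) int codes
    pmj_nodes: np.ndarray          # (P,) tree node ids (leaves)
    pmj_myo_nodes: np.ndarray      # (P,) myocardial mesh node ids
    cv: float = _cfg.PURKINJE_CV                 # mm/ms (= m/s)
    pmj_delay_antero: float = 5.0  # ms
    pmj_delay_retro: float = 3.0   # ms
    his_node: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.edges[:, 1]]
                              - self.nodes[self.edges[:, 0]], axis=1)

    def copy(self) -> "PurkinjeTree":
        return replace(self, edge_blocked=self.edge_blocked.copy())


@dataclass(frozen=True)
class TreeActivation:
    """Activation time per tree node (inf when unreached)."""

    activation_time: np.ndarray


@dataclass(frozen=True)
class GrowthParams:
    """Knobs of the stochastic growth (desk-scale defaults)."""

    pmj_density_per_mm2: float = 0.03
    cv: float = _cfg.PURKINJE_CV
    pmj_delay_antero: float = 5.0
    pmj_delay_retro: float = 3.0
    stem_height_mm: float = 3.0


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def _surface_graph(coords: np.ndarray, h: float):
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(1.5 * h)))
    if pairs.size == 0:
        raise ValueError("surface too small to build a Purkinje graph")
    w = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    n = coords.shape[0]
    A = sp.coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([pairs[:, 0], pairs[:, 1]]),
                        np.concatenate([pairs[:, 1], pairs[:, 0]]))),
                      shape=(n, n)).tocsr()
    return A


def _pick(coords: np.ndarray, score: np.ndarray) -> int:
    return int(np.argmin(score))


def grow_tree(mesh: Mesh, seed: int,
              params: GrowthParams = GrowthParams()) -> PurkinjeTree:
    """Grow the stochastic conduction tree on the endocardial surfaces.

    Deterministic for a fixed seed.  Raises when a surface has fewer
    candidate sites than the requested PMJ count.
    """
    h = mesh.edge_length
    rng = np.random.default_rng(seed)

    lv_ids = np.where(mesh.surface_tags == TAG_LV_ENDO)[0]
    rv_ids = np.where(mesh.surface_tags == TAG_RV_ENDO)[0]
    if lv_ids.size < 20 or rv_ids.size < 20:
        raise ValueError("mesh lacks tagged endocardial surfaces")

    # septal RV endo nodes (for entry/targets)
    sep_elems = mesh.region == REGION_SEPTUM
    sep_nodes = np.unique(mesh.hex_elements[sep_elems])

    out_nodes: list[np.ndarray] = []
    out_edges: list[tuple[int, int, int]] = []   # (a, b, label)

    def _add_node(p) -> int:
        out_nodes.append(np.asarray(p, dtype=float))
        return len(out_nodes) - 1

    pmj_tree_nodes: list[int] = []
    pmj_myo: list[int] = []

    # --- stem geometry ----------------------------------------------------
    # The left bundle breaks out high on the LV septal endocardium; the
    # right bundle is a long thin fascicle that only arborises near the
    # apical third of the septum, which is what delays RV activation
    # relative to the LV under intrinsic conduction.
    def _entry(ids, height_frac):
        on_sep = np.isin(ids, sep_nodes)
        cand = ids[on_sep] if on_sep.any() else ids
        cc = mesh.node_coords[cand]
        z_lo, z_hi = cc[:, 2].min(), cc[:, 2].max()
        zf = (cc[:, 2] - z_lo) / max(z_hi - z_lo, 1e-9)
        score = np.abs(zf - height_frac) + 0.02 * np.abs(cc[:, 1])
        return int(cand[np.argmin(score)])

    lv_entry_mesh = _entry(lv_ids, 0.85)
    rv_entry_mesh = _entry(rv_ids, 0.30)
    p_lv = mesh.node_coords[lv_entry_mesh]
    p_rv = mesh.node_coords[rv_entry_mesh]
    p_his = 0.5 * (p_lv + p_rv) + np.array([0.0, 0.0, params.stem_height_mm])

    his = _add_node(p_his)                      # node 0
    # left bundle: chain of 3 linear elements (two are the LBBB lesion site)
    lb1 = _add_node(p_his + (p_lv - p_his) / 3.0)
    lb2 = _add_node(p_his + 2.0 * (p_lv - p_his) / 3.0)
    # right bundle: chain of 2
    rb1 = _add_node(0.5 * (p_his + p_rv))

    def _grow_ventricle(ids, entry_mesh, branch_targets, n_pmj):
        """Returns local->global node map after adding this ventricle."""
        coords = mesh.node_coords[ids]
        A = _surface_graph(coords, h)
        entry_local = int(np.where(ids == entry_mesh)[0][0])
        dist, pred = dijkstra(A, indices=entry_local, return_predecessors=True)
        reachable = np.isfinite(dist)

        used = {}                       # local surface idx -> tree node id
        def _node_for(li) -> int:
            if li not in used:
                used[li] = _add_node(coords[li])
            return used[li]

        edge_set = {}                   # (a_local, b_local) -> label

        def _path_edges(li, label):
            while pred[li] >= 0:
                pa = pred[li]
                key = (min(pa, li), max(pa, li))
                if key in edge_set:
                    li = pa
                    continue
                edge_set[key] = label
                li = pa

        # main branches first (fixed corridors)
        for label, target_local in branch_targets:
            _path_edges(target_local, label)

        # stochastic PMJ sites; every main-branch terminal is a junction
        # too (anatomically, the fascicle endpoints arborise into PMJs)
        cand = np.where(reachable)[0]
        cand = cand[cand != entry_local]
        if n_pmj > cand.size:
            raise ValueError(
                f"surface too small for requested PMJ density: "
                f"{n_pmj} junctions for {cand.size} candidate sites")
        chosen = list(rng.choice(cand, size=n_pmj, replace=False))
        chosen += [t for _, t in branch_targets if t not in chosen]
        for li in chosen:
            _path_edges(int(li), BR_TERMINAL)

        for (a, b), label in edge_set.items():
            out_edges.append((_node_for(a), _node_for(b), label))

        # PMJs = chosen sites that remain leaves of the final subtree
        degree = {}
        for (a, b) in edge_set:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        for li in chosen:
            if degree.get(int(li), 0) == 1:
                pmj_tree_nodes.append(used[int(li)])
                pmj_myo.append(int(ids[int(li)]))
        return _node_for(entry_local)

    # --- LV section: 3 main branches -------------------------------------
    lv_coords = mesh.node_coords[lv_ids]
    psi = np.arctan2(lv_coords[:, 1], -lv_coords[:, 0])  # 0 = lateral
    zc = lv_coords[:, 2]
    z_lo, z_hi = zc.min(), zc.max()
    zf = (zc - z_lo) / max(z_hi - z_lo, 1e-9)

    def _lv_target(psi0, zf0):
        score = np.abs(psi - psi0) + 2.0 * np.abs(zf - zf0)
        return int(np.argmin(score))

    lv_area = lv_ids.size * h * h
    rv_area = rv_ids.size * h * h
    n_lv = int(round(params.pmj_density_per_mm2 * lv_area))
    n_rv = int(round(params.pmj_density_per_mm2 * rv_area))

    lv_targets = [(BR_LV_POST, _lv_target(-1.8, 0.45)),
                  (BR_LV_SEPT, _lv_target(0.0, 0.02)),   # toward the apex
                  (BR_LV_ANT, _lv_target(+1.8, 0.45))]
    lv_entry_tree = _grow_ventricle(lv_ids, lv_entry_mesh, lv_targets, n_lv)

    # --- RV section: 2 main branches -------------------------------------
    rv_coords = mesh.node_coords[rv_ids]
    rzc = rv_coords[:, 2]
    rz_lo, rz_hi = rzc.min(), rzc.max()
    rzf = (rzc - rz_lo) / max(rz_hi - rz_lo, 1e-9)
    ry = rv_coords[:, 1]
    rv_on_sep = np.isin(rv_ids, sep_nodes)

    def _rv_target(kind):
        if kind == "apex":
            # the septal apex, selected by the same rule as the RV apex
            # pacing site: apical pacing then sits on the arborised
            # fascicle terminal, which is what makes it enter the
            # conduction system quickly
            cand = np.where(rv_on_sep)[0] if rv_on_sep.any() \
                else np.arange(rv_ids.size)
            cc = rv_coords[cand]
            score = (cc[:, 2] - cc[:, 2].min()) + 0.05 * np.abs(cc[:, 1])
            return int(cand[np.argmin(score)])
        # anterior free wall, mid height (moderator-band region)
        score = np.abs(rzf - 0.5) + np.where(ry > 0, 0.0, 2.0) \
            - 0.02 * rv_coords[:, 0]
        return int(np.argmin(score))

    rv_targets = [(BR_RV_SEPT, _rv_target("apex")),
                  (BR_RV_ANT, _rv_target("ant"))]
    rv_entry_tree = _grow_ventricle(rv_ids, rv_entry_mesh, rv_targets, n_rv)

    # --- stem edges -------------------------------------------------------
    out_edges.append((his, lb1, BR_LBB))
    out_edges.append((lb1, lb2, BR_LBB))
    out_edges.append((lb2, lv_entry_tree, BR_LBB))
    out_edges.append((his, rb1, BR_RBB))
    out_edges.append((rb1, rv_entry_tree, BR_RBB))

    nodes = np.vstack(out_nodes)
    edges = np.array([(a, b) for a, b, _ in out_edges], dtype=np.int64)
    labels = np.array([lab for _, _, lab in out_edges], dtype=np.int8)
    tree = PurkinjeTree(
        nodes=nodes, edges=edges,
        edge_blocked=np.zeros(edges.shape[0], dtype=bool),
        branch_label=labels,
        pmj_nodes=np.asarray(pmj_tree_nodes, dtype=np.int64),
        pmj_myo_nodes=np.asarray(pmj_myo, dtype=np.int64),
        cv=params.cv,
        pmj_delay_antero=params.pmj_delay_antero,
        pmj_delay_retro=params.pmj_delay_retro,
        his_node=his,
    )
    return tree


# ---------------------------------------------------------------------------
# conduction
# ---------------------------------------------------------------------------


def _adjacency_ms(tree: PurkinjeTree) -> sp.csr_matrix:
    keep = ~tree.edge_blocked
    e = tree.edges[keep]
    w = tree.edge_lengths()[keep] / tree.cv
    n = tree.n_nodes
    return sp.coo_matrix((np.concatenate([w, w]),
                          (np.concatenate([e[:, 0], e[:, 1]]),
                           np.concatenate([e[:, 1], e[:, 0]]))),
                         shape=(n, n)).tocsr()


def propagate_tree(tree: PurkinjeTree, sources: Sequence[tuple],
                   initial: Optional[np.ndarray] = None) -> TreeActivation:
    """Earliest activation per tree node from onset sources.

    ``sources`` is a sequence of (node, onset_ms).  Path lengths run over
    non-blocked edges at constant velocity; with several sources each
    node takes the elementwise minimum (Dijkstra semantics, implemented
    with a virtual super-source).  ``initial`` optionally seeds every
    node with an existing activation time.
    """
    n = tree.n_nodes
    if not sources and initial is None:
        return TreeActivation(np.full(n, np.inf))
    A = _adjacency_ms(tree).tocoo()
    rows = list(A.row + 1)
    cols = list(A.col + 1)
    vals = list(A.data)
    # virtual super-source edges; duplicates must combine by minimum
    # (sparse assembly would otherwise sum them)
    virtual: dict[int, float] = {}
    for node, onset in sources:
        if not 0 <= node < n:
            raise ValueError(f"source node {node} outside the tree")
        if onset < 0:
            raise ValueError("source onset must be >= 0")
        virtual[node] = min(virtual.get(node, np.inf), float(onset))
    if initial is not None:
        for node, onset in enumerate(initial):
            if np.isfinite(onset):
                virtual[node] = min(virtual.get(node, np.inf), float(onset))
    for node, onset in virtual.items():
        rows.append(0)
        cols.append(node + 1)
        vals.append(onset)
    G = sp.coo_matrix((vals, (rows, cols)), shape=(n + 1, n + 1)).tocsr()
    dist = dijkstra(G, directed=True, indices=0)
    return TreeActivation(dist[1:])


def apply_lbbb(tree: PurkinjeTree) -> PurkinjeTree:
    """Left bundle branch block: null conductivity in the two linear
    elements of the left bundle proximal to its trifurcation."""
    lbb = np.where(tree.branch_label == BR_LBB)[0]
    if lbb.size < 2:
        raise ValueError("tree has no (or too few) left-bundle elements")
    # proximal = nearest to the His node along the unblocked tree
    base = propagate_tree(tree, [(tree.his_node, 0.0)]).activation_time
    prox = lbb[np.argsort(np.minimum(base[tree.edges[lbb, 0]],
                                     base[tree.edges[lbb, 1]]))[:2]]
    out = tree.copy()
    out.edge_blocked[prox] = True
    return out


def couple_pmjs(tree_activation: TreeActivation,
                myocardial_activation: np.ndarray,
                tree: PurkinjeTree,
                direction: str):
    """PMJ transfer events in one direction.

    ANTERO: each PMJ whose tree time is finite emits a myocardial
    stimulus event (myo_node, tree_time + antero delay) unless the
    myocardium there activated earlier.  RETRO: each PMJ whose paired
    myocardial node has activated emits a tree source event
    (tree_node, myo_time + retro delay) unless the tree node activated
    earlier.  Returns a list of (node, time) events.
    """
    if direction not in ("ANTERO", "RETRO"):
        raise ValueError("direction must be 'ANTERO' or 'RETRO'")
    ta = tree_activation.activation_time
    events = []
    for tn, mn in zip(tree.pmj_nodes, tree.pmj_myo_nodes):
        if direction == "ANTERO":
            if np.isfinite(ta[tn]):
                fire = ta[tn] + tree.pmj_delay_antero
                if not (np.isfinite(myocardial_activation[mn])
                        and myocardial_activation[mn] <= fire):
                    events.append((int(mn), float(fire)))
        else:
            tm = myocardial_activation[mn]
            if np.isfinite(tm):
                fire = tm + tree.pmj_delay_retro
                if not (np.isfinite(ta[tn]) and ta[tn] <= fire):
                    events.append((int(tn), float(fire)))
    return events


# ---------------------------------------------------------------------------
# Stewart-cable mode (velocity calibration)
# ---------------------------------------------------------------------------


def purkinje_cable_cv(diffusivity: float = _cfg.PURKINJE_CABLE_DIFFUSIVITY,
                      length_mm: float = 30.0, dx: float = 0.4,
                      dt: float = 0.01, stim_amp: float = 80.0,
                      stim_dur: float = 1.0) -> float:
    """Conduction velocity (m/s) of a straight 1D Stewart-model cable.

    A stimulus at one end; velocity measured between interior probes at
    30% and 70% of the cable (activation = -10 mV upward crossing).
    """
    from .cells.stewart import stewart_step, N_STATES
    from .cells import stewart_initial_state

    n = int(round(length_mm / dx)) + 1
    S = np.tile(stewart_initial_state(), (n, 1))
    # 1D second difference with zero-flux ends
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0
    L = sp.diags([np.ones(n - 1), main, np.ones(n - 1)], [-1, 0, 1],
                 format="csr") * (diffusivity / dx / dx)
    # end nodes own half a dual cell: scale their flux divergence
    m = np.ones(n)
    m[0] = m[-1] = 0.5
    L = sp.diags(1.0 / m) @ L
    act = np.full(n, np.inf)
    istim = np.zeros(n)
    pa, pb = int(0.3 * (n - 1)), int(0.7 * (n - 1))
    t = 0.0
    max_t = 80.0
    step = 0
    while t < max_t:
        istim[:] = 0.0
        if t < stim_dur:
            istim[:2] = stim_amp
        V = S[:, 0]
        V += dt * (L @ V)
        stewart_step(S, istim, dt)
        step += 1
        t = step * dt
        newly = np.isinf(act) & (S[:, 0] >= -10.0)
        act[newly] = t
        if np.isfinite(act[pa]) and np.isfinite(act[pb]):
            break
    if not (np.isfinite(act[pa]) and np.isfinite(act[pb])):
        raise RuntimeError("cable failed to propagate to both probes")
    return float((pb - pa) * dx / (act[pb] - act[pa]))


def calibrate_purkinje_cable(target_cv: float = _cfg.PURKINJE_CV,
                             tol: float = 0.01, **cable_kwargs) -> float:
    """Secant search for the cable diffusivity that yields ``target_cv``.

    Returns the calibrated diffusivity (mm^2/ms); the graph-propagation
    mode then uses the measured velocity.
    """
    d0, d1 = 1.0, 2.0
    c0 = purkinje_cable_cv(d0, **cable_kwargs)
    c1 = purkinje_cable_cv(d1, **cable_kwargs)
    for _ in range(12):
        if abs(c1 - target_cv) <= tol:
            return d1
        if c1 == c0:
            break
        d2 = d1 + (target_cv - c1) * (d1 - d0) / (c1 - c0)
        d2 = max(d2, 1e-3)
        d0, c0 = d1, c1
        d1 = d2
        c1 = purkinje_cable_cv(d1, **cable_kwargs)
    return d1
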