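"""Synthetic cardiac geometry.

Builds the two computational domains the pipeline runs on:

* a regular slab of hexahedral voxels used for conduction-velocity
  calibration, and
* a desk-scale biventricular mesh made of two communicating truncated
  ellipsoids (LV thick-walled, RV crescent) with rule-based rotating
  fibers, transmural cell-type layers (endo/mid/epi), region labels
  (septum, RV free wall, 9 LV free-wall segments, apex, base) and
  tagged endocardial/epicardial surfaces.

All lengths are millimetres.  Meshes are voxel (structured hexahedral)
meshes with element-centred fibers and node-centred potentials; node and
element ordering is deterministic, so identical parameters give
bit-identical meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# label codes
# ---------------------------------------------------------------------------

CELL_ENDO, CELL_MID, CELL_EPI = 0, 1, 2
CELLTYPE_NAMES = {CELL_ENDO: "ENDO", CELL_MID: "MID", CELL_EPI: "EPI"}

# LV free-wall segments use codes 1..9; other regions sit above them.
REGION_UNASSIGNED = 0            # slabs and other non-anatomical meshes
REGION_SEPTUM = 20
REGION_RV_FREEWALL = 21
REGION_APEX = 22
REGION_BASE = 23
REGION_LV_FREEWALL = 24          # pre-segmentation blanket label

SEG_CIRC = ("POSTERIOR", "LATERAL", "ANTERIOR")
SEG_LONG = ("APICAL", "MID", "BASAL")


def segment_code(circ: str, level: str) -> int:
    """Map (circumferential, longitudinal) names to LV segment codes 1..9."""
    return SEG_CIRC.index(circ) * 3 + SEG_LONG.index(level) + 1


def segment_name(code: int) -> str:
    if not 1 <= code <= 9:
        raise ValueError(f"not an LV free-wall segment code: {code}")
    circ, level = divmod(code - 1, 3)
    return f"{SEG_CIRC[circ]}_{SEG_LONG[level]}"


TAG_NONE, TAG_LV_ENDO, TAG_RV_ENDO, TAG_EPI = 0, 1, 2, 3

RV_LEAD_LABELS = ("RV_APEX", "RV_MID", "RV_UPPER")
# fractional apex->base height of the RV septal sites (mid / upper-outflow)
RV_SITE_HEIGHT = {"RV_APEX": 0.0, "RV_MID": 0.50, "RV_UPPER": 0.85}

LEAD_CUBE_VOLUME_MM3 = 0.5       # pacing electrodes modelled as 0.5 mm^3 cubes


def lv_lead_labels() -> list[str]:
    """All 18 LV lead labels: 9 segments x {EPI, ENDO}."""
    out = []
    for code in range(1, 10):
        for surf in ("EPI", "ENDO"):
            out.append(f"LV_{segment_name(code)}_{surf}")
    return out


def all_lead_labels() -> list[str]:
    return list(RV_LEAD_LABELS) + lv_lead_labels()


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Structured hexahedral mesh restricted to a myocardial voxel mask.

    ``hex_elements`` uses VTK hexahedron corner ordering.  ``depth`` is the
    normalised transmural coordinate (0 endocardium, 1 epicardium) and
    ``normals`` the outward transmural direction, both element-centred;
    they are only present on biventricular meshes.
    """

    node_coords: np.ndarray          # (N, 3) float64, mm
    hex_elements: np.ndarray         # (E, 8) int32
    fiber_dirs: np.ndarray           # (E, 3) float64, unit
    celltype: np.ndarray             # (E,)  int8
    region: np.ndarray               # (E,)  int16
    surface_tags: np.ndarray         # (N,)  int8
    edge_length: float
    origin: np.ndarray               # (3,) grid origin (node 0,0,0)
    grid_shape: tuple[int, int, int]  # voxel counts per axis
    voxel_ijk: np.ndarray            # (E, 3) int32 voxel indices
    node_gid: np.ndarray             # (N,) linear index in the full node grid
    depth: Optional[np.ndarray] = None      # (E,) in [0, 1]
    normals: Optional[np.ndarray] = None    # (E, 3)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hex_elements.shape[0]

    def element_centers(self) -> np.ndarray:
        return self.node_coords[self.hex_elements].mean(axis=1)

    def validate(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.hex_elements.min() < 0 or self.hex_elements.max() >= self.n_nodes:
            raise ValueError("element connectivity indices out of range")
        norms = np.linalg.norm(self.fiber_dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fiber directions must be unit vectors")


PRECORDIAL_LABELS = ("V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Precordial electrodes V1..V6 plus three distal reference sites
    whose mean potential serves as the Wilson-central-terminal surrogate."""

    precordial_positions: np.ndarray   # (6, 3) mm, ordered V1..V6
    reference_positions: np.ndarray    # (3, 3) mm
    bath_conductivity: float = 0.2     # S/m, metadata for FEM backends

    def __post_init__(self):
        if np.asarray(self.precordial_positions).shape != (6, 3):
            raise ValueError("exactly six precordial electrodes required")
        if np.asarray(self.reference_positions).shape != (3, 3):
            raise ValueError("exactly three reference positions required")


@dataclass(frozen=True)
class LeadSite:
    """A pacing-electrode site: the mesh nodes inside a 0.5 mm^3 cube."""

    label: str
    center: np.ndarray               # (3,)
    node_set: np.ndarray             # (k,) node ids


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

# VTK hexahedron corner offsets (i, j, k) order
_HEX_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], dtype=np.int64)


def _mesh_from_mask(mask: np.ndarray, origin: np.ndarray, edge: float) -> Mesh:
    """Extract the hexahedral mesh of all True voxels in ``mask``."""
    nx, ny, nz = mask.shape
    vox = np.argwhere(mask).astype(np.int64)
    if vox.size == 0:
        raise ValueError("empty voxel mask: no myocardial elements")
    # node grid is (nx+1, ny+1, nz+1); linear id with k fastest
    mx, my, mz = nx + 1, ny + 1, nz + 1
    corner = vox[:, None, :] + _HEX_OFFSETS[None, :, :]
    gid = (corner[..., 0] * my + corner[..., 1]) * mz + corner[..., 2]
    node_gid, inv = np.unique(gid, return_inverse=True)
    elements = inv.reshape(-1, 8).astype(np.int32)
    kk = node_gid % mz
    jj = (node_gid // mz) % my
    ii = node_gid // (mz * my)
    coords = origin[None, :] + edge * np.stack([ii, jj, kk], axis=1).astype(float)
    E = elements.shape[0]
    fibers = np.zeros((E, 3))
    fibers[:, 0] = 1.0
    return Mesh(
        node_coords=coords,
        hex_elements=elements,
        fiber_dirs=fibers,
        celltype=np.zeros(E, dtype=np.int8),
        region=np.full(E, REGION_UNASSIGNED, dtype=np.int16),
        surface_tags=np.zeros(coords.shape[0], dtype=np.int8),
        edge_length=float(edge),
        origin=np.asarray(origin, dtype=float),
        grid_shape=(nx, ny, nz),
        voxel_ijk=vox.astype(np.int32),
        node_gid=node_gid,
    )


def build_slab(dims_mm, edge_mm: float, fiber_axis=(1.0, 0.0, 0.0)) -> Mesh:
    """Regular hexahedral slab with uniform fibers, for CV calibration.

    ``dims_mm`` must be (near-)integer multiples of ``edge_mm``.
    Cell type is uniformly endocardial.
    """
    dims = np.asarray(dims_mm, dtype=float)
    if np.any(dims <= 0) or edge_mm <= 0:
        raise ValueError("slab dimensions and edge length must be positive")
    n = dims / edge_mm
    n_round = np.rint(n)
    if np.any(np.abs(n - n_round) > 1e-6) or np.any(n_round < 1):
        raise ValueError(f"edge {edge_mm} mm does not divide slab dims {dims_mm}")
    shape = tuple(int(v) for v in n_round)
    mask = np.ones(shape, dtype=bool)
    mesh = _mesh_from_mask(mask, origin=np.zeros(3), edge=float(edge_mm))
    axis = np.asarray(fiber_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("fiber_axis must be a nonzero vector")
    mesh.fiber_dirs[:] = axis / nrm
    mesh.celltype[:] = CELL_ENDO
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# biventricular geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiventricleParams:
    """Paired truncated-ellipsoid biventricle.

    The LV is a thick-walled half-ellipsoid with long axis along -z and
    base cut at z = 0; the RV is a thinner crescent formed by a second
    ellipsoid shifted along +x whose cavity abuts the LV epicardial
    surface (the shared wall becomes the septum).  Defaults are a
    desk-scale stand-in for an adult human biventricle.
    """

    lv_semi_axes: tuple[float, float, float] = (30.0, 30.0, 45.0)
    lv_wall: float = 9.0
    rv_wall: float = 4.0
    # RV ellipsoid, relative to the LV semi-axes
    rv_center_frac: tuple[float, float, float] = (0.55, 0.0, 0.0)
    rv_semi_frac: tuple[float, float, float] = (0.95, 0.80, 0.80)
    base_margin_frac: float = 0.04   # top layer labelled BASE
    apex_margin_frac: float = 0.06   # bottom layer labelled APEX
    edge_mm: float = 0.8

    def scaled(self, factor: float, edge_mm: float) -> "BiventricleParams":
        a, b, c = self.lv_semi_axes
        return replace(
            self,
            lv_semi_axes=(a * factor, b * factor, c * factor),
            lv_wall=self.lv_wall * factor,
            rv_wall=max(self.rv_wall * factor, 3.0 * edge_mm),
            edge_mm=edge_mm,
        )


def _ellipsoid(x, y, z, center, semi):
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2)


def build_biventricle(params: BiventricleParams = BiventricleParams()) -> Mesh:
    """Voxelise the paired-ellipsoid biventricle and derive all fields.

    Returns a mesh with surface tags (LV_ENDO / RV_ENDO / EPI), region
    labels (SEPTUM, RV_FREEWALL, APEX, BASE, LV_FREEWALL), the normalised
    transmural depth and outward transmural normals.  Fibers are left
    along +x; call :func:`assign_fibers_streeter` afterwards.
    """
    a, b, c = params.lv_semi_axes
    w = params.lv_wall
    wr = params.rv_wall
    h = params.edge_mm
    if w <= 0 or wr <= 0 or min(a, b, c) <= w:
        raise ValueError("degenerate ventricular radii: wall thickness must be "
                         "positive and smaller than every LV semi-axis")
    if w <= wr:
        raise ValueError("LV wall must be thicker than RV wall")
    if h > min(w, wr) / 3.0 + 1e-12:
        raise ValueError(
            f"edge {h} mm too coarse: must be <= min wall thickness / 3 "
            f"({min(w, wr) / 3.0:.3f} mm)")

    rv_center = (params.rv_center_frac[0] * a,
                 params.rv_center_frac[1] * b,
                 params.rv_center_frac[2] * c)
    rv_semi = (params.rv_semi_frac[0] * a,
               params.rv_semi_frac[1] * b,
               params.rv_semi_frac[2] * c)
    rv_semi_in = tuple(s - wr for s in rv_semi)

    # bounding box (one voxel of padding all round)
    x_lo = min(-a, rv_center[0] - rv_semi[0]) - h
    x_hi = max(a, rv_center[0] + rv_semi[0]) + h
    y_lo, y_hi = -max(b, rv_semi[1]) - h, max(b, rv_semi[1]) + h
    z_lo, z_hi = -c - h, 0.0
    nx = int(np.ceil((x_hi - x_lo) / h))
    ny = int(np.ceil((y_hi - y_lo) / h))
    nz = int(np.ceil((z_hi - z_lo) / h))
    origin = np.array([x_lo, y_lo, z_hi - nz * h])

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    x = origin[0] + (ii + 0.5) * h
    y = origin[1] + (jj + 0.5) * h
    z = origin[2] + (kk + 0.5) * h

    below_base = z <= -1e-9
    f_lv_out = _ellipsoid(x, y, z, (0, 0, 0), (a, b, c))
    f_lv_in = _ellipsoid(x, y, z, (0, 0, 0), (a - w, b - w, c - w))
    f_rv_out = _ellipsoid(x, y, z, rv_center, rv_semi)
    f_rv_in = _ellipsoid(x, y, z, rv_center, rv_semi_in)

    lv_cav = (f_lv_in <= 1.0) & below_base
    lv_wall = (f_lv_out <= 1.0) & (f_lv_in > 1.0) & below_base
    rv_cav = (f_rv_in <= 1.0) & (f_lv_out > 1.0) & below_base
    rv_wall = (f_rv_out <= 1.0) & (f_rv_in > 1.0) & (f_lv_out > 1.0) & below_base
    myo = lv_wall | rv_wall
    outside = ~(myo | lv_cav | rv_cav)

    mesh = _mesh_from_mask(myo, origin=origin, edge=h)
    vox = mesh.voxel_ijk
    vi, vj, vk = vox[:, 0], vox[:, 1], vox[:, 2]

    # --- regions -----------------------------------------------------------
    region = np.full(mesh.n_elements, REGION_LV_FREEWALL, dtype=np.int16)
    septum = lv_wall & (f_rv_out <= 1.0)
    region[septum[vi, vj, vk]] = REGION_SEPTUM
    region[rv_wall[vi, vj, vk]] = REGION_RV_FREEWALL
    zc = z[vi, vj, vk]
    region[zc < -c * (1.0 - params.apex_margin_frac)] = REGION_APEX
    region[zc > -c * params.base_margin_frac] = REGION_BASE
    mesh.region = region

    # --- surface tags ------------------------------------------------------
    # priority at shared nodes: LV endo > RV endo > epi (tag in that order)
    tags = np.zeros((nx + 1, ny + 1, nz + 1), dtype=np.int8)
    _PRIO = {TAG_NONE: 0, TAG_EPI: 1, TAG_RV_ENDO: 2, TAG_LV_ENDO: 3}

    def _tag_faces(neighbor_mask, tag):
        padded = np.pad(neighbor_mask, 1, constant_values=False)
        for axis in range(3):
            for sgn in (0, 1):  # 0: -axis neighbour, 1: +axis neighbour
                sl = [slice(1, -1)] * 3
                off = -1 if sgn == 0 else 1
                sl[axis] = slice(1 + off, padded.shape[axis] - 1 + off)
                nb = padded[tuple(sl)]
                facing = myo & nb
                if not facing.any():
                    continue
                base_corner = np.argwhere(facing)
                base_corner[:, axis] += sgn
                others = [ax for ax in range(3) if ax != axis]
                for d0 in (0, 1):
                    for d1 in (0, 1):
                        node = base_corner.copy()
                        node[:, others[0]] += d0
                        node[:, others[1]] += d1
                        idx = (node[:, 0], node[:, 1], node[:, 2])
                        cur = tags[idx]
                        prio = np.zeros_like(cur)
                        for t_, p_ in _PRIO.items():
                            prio[cur == t_] = p_
                        tags[idx] = np.where(_PRIO[tag] > prio, tag, cur)

    _tag_faces(outside, TAG_EPI)
    _tag_faces(rv_cav, TAG_RV_ENDO)
    _tag_faces(lv_cav, TAG_LV_ENDO)
    mesh.surface_tags = tags.ravel()[mesh.node_gid].astype(np.int8)

    # --- transmural depth --------------------------------------------------
    # Signed distances to the bounding ellipsoid surfaces, estimated
    # analytically as (level - 1) / |grad level| of s = sqrt(f); this is
    # sub-voxel accurate and immune to the artificial base-cut plane.
    # The epicardial side of the LV wall is whichever is nearer of the
    # outer shell and the RV cavity, so the septum runs LV-endo -> RV-endo.
    xc, yc, zc = x[vi, vj, vk], y[vi, vj, vk], z[vi, vj, vk]

    def _level_dist(center, semi):
        """Signed mm distance to the ellipsoid surface (>0 outside)."""
        dx = (xc - center[0]) / semi[0]
        dy = (yc - center[1]) / semi[1]
        dz = (zc - center[2]) / semi[2]
        s = np.sqrt(dx * dx + dy * dy + dz * dz)
        grad = np.sqrt((dx / semi[0]) ** 2 + (dy / semi[1]) ** 2
                       + (dz / semi[2]) ** 2) / np.maximum(s, 1e-12)
        return (s - 1.0) / np.maximum(grad, 1e-12)

    d_lv_endo = _level_dist((0, 0, 0), (a - w, b - w, c - w))
    d_lv_epi = -_level_dist((0, 0, 0), (a, b, c))   # also the septal RV face
    d_rv_endo = _level_dist(rv_center, rv_semi_in)
    d_rv_epi = -_level_dist(rv_center, rv_semi)

    rvw_e = rv_wall[vi, vj, vk]
    a_side = np.maximum(d_lv_endo, 0.0)
    b_side = np.maximum(d_lv_epi, 0.0)
    a_side[rvw_e] = np.maximum(d_rv_endo, 0.0)[rvw_e]
    b_side[rvw_e] = np.maximum(d_rv_epi, 0.0)[rvw_e]
    mesh.depth = np.clip(a_side / np.maximum(a_side + b_side, 1e-12), 0.0, 1.0)

    # --- outward transmural normals (analytic ellipsoid gradients) ---------
    xc, yc = x[vi, vj, vk], y[vi, vj, vk]
    n_lv = np.stack([2 * xc / a**2, 2 * yc / b**2, 2 * zc / c**2], axis=1)
    n_rv = np.stack([2 * (xc - rv_center[0]) / rv_semi[0]**2,
                     2 * (yc - rv_center[1]) / rv_semi[1]**2,
                     2 * (zc - rv_center[2]) / rv_semi[2]**2], axis=1)
    normals = n_lv.copy()
    normals[rvw_e] = n_rv[rvw_e]
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    mesh.normals = normals / nrm

    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# fibers and layers
# ---------------------------------------------------------------------------


def assign_fibers_streeter(mesh: Mesh, endo_helix_deg: float = 60.0,
                           epi_helix_deg: float = -60.0,
                           transmural_deg_endo: float = 0.0,
                           transmural_deg_epi: float = 0.0) -> Mesh:
    """Rule-based rotating-fiber field.

    The helix angle interpolates linearly in normalised transmural depth
    from ``endo_helix_deg`` (depth 0) to ``epi_helix_deg`` (depth 1);
    fibers lie in the wall-tangent plane spanned by the circumferential
    and longitudinal directions.  A linear transmural-angle rule is
    available but defaults to zero (the conduction-velocity calibration
    assumes in-plane fibers).
    """
    if mesh.depth is None or mesh.normals is None:
        raise ValueError("mesh has no surface/depth information; "
                         "fibers can only be assigned on the biventricle")
    t = mesh.depth
    alpha_h = np.deg2rad(endo_helix_deg + (epi_helix_deg - endo_helix_deg) * t)
    alpha_t = np.deg2rad(transmural_deg_endo
                         + (transmural_deg_epi - transmural_deg_endo) * t)

    n = mesh.normals
    zhat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(zhat, n.shape), n)
    cn = np.linalg.norm(circ, axis=1, keepdims=True)
    degen = cn[:, 0] < 1e-8
    if degen.any():
        alt = np.cross(np.broadcast_to(np.array([1.0, 0.0, 0.0]), n.shape), n)
        circ[degen] = alt[degen]
        cn = np.linalg.norm(circ, axis=1, keepdims=True)
    circ = circ / cn
    longd = np.cross(n, circ)

    in_plane = (np.cos(alpha_h)[:, None] * circ
                + np.sin(alpha_h)[:, None] * longd)
    fibers = (np.cos(alpha_t)[:, None] * in_plane
              + np.sin(alpha_t)[:, None] * n)
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    mesh.fiber_dirs = fibers
    mesh.validate()
    return mesh


DEFAULT_LAYER_FRACTIONS = (0.17, 0.41, 0.42)


def assign_transmural_layers(mesh: Mesh,
                             fractions=DEFAULT_LAYER_FRACTIONS) -> Mesh:
    """Assign endo/mid/epi cell types by transmural depth.

    Intervals are half-open and lower-inclusive: depth in [0, f_endo) is
    ENDO, [f_endo, f_endo + f_mid) is MID, the rest EPI.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise ValueError("layer fractions must be three nonnegative numbers "
                         "summing to 1")
    if mesh.depth is None:
        raise ValueError("mesh has no transmural depth field")
    t = mesh.depth
    ct = np.full(mesh.n_elements, CELL_EPI, dtype=np.int8)
    ct[t < fr[0] + fr[1]] = CELL_MID
    ct[t < fr[0]] = CELL_ENDO
    mesh.celltype = ct
    return mesh


# ---------------------------------------------------------------------------
# LV free-wall segmentation and lead sites
# ---------------------------------------------------------------------------


def segment_lv_free_wall(mesh: Mesh) -> Mesh:
    """Partition the LV free wall into 3 circumferential x 3 longitudinal
    segments (posterior/lateral/anterior x apical/mid/basal)."""
    fw = mesh.region == REGION_LV_FREEWALL
    if not fw.any():
        raise ValueError("mesh has no LV free-wall region (slab meshes "
                         "cannot be segmented)")
    centers = mesh.element_centers()[fw]
    # angle about the LV long axis, 0 at the anti-septal (lateral) direction;
    # negative toward posterior (y < 0), positive toward anterior
    psi = np.arctan2(centers[:, 1], -centers[:, 0])
    zc = centers[:, 2]
    psi_bins = np.quantile(psi, [1.0 / 3.0, 2.0 / 3.0])
    z_bins = np.quantile(zc, [1.0 / 3.0, 2.0 / 3.0])
    circ_idx = np.digitize(psi, psi_bins)          # 0 post, 1 lat, 2 ant
    long_idx = np.digitize(zc, z_bins)             # 0 apical .. 2 basal
    codes = (circ_idx * 3 + long_idx + 1).astype(np.int16)
    region = mesh.region.copy()
    region[np.where(fw)[0]] = codes
    mesh.region = region
    return mesh


def _surface_nodes_of_elements(mesh: Mesh, elem_mask: np.ndarray,
                               tag: int) -> np.ndarray:
    nodes = np.unique(mesh.hex_elements[elem_mask])
    return nodes[mesh.surface_tags[nodes] == tag]


def place_lead(mesh: Mesh, label: str) -> LeadSite:
    """Locate a pacing site and gather the nodes of its 0.5 mm^3 cube.

    RV sites sit on the RV septal endocardium (apex, or 50% / 85% of the
    apex-to-base septal height); LV sites sit at the middle of the named
    free-wall segment on the requested surface.  If the cube contains no
    mesh node (coarse grids), the site snaps to the nearest surface node.
    """
    label = label.upper()
    if label in RV_LEAD_LABELS:
        sep = np.isin(mesh.region, [REGION_SEPTUM])
        cand = _surface_nodes_of_elements(mesh, sep, TAG_RV_ENDO)
        if cand.size == 0:
            raise ValueError("no RV septal endocardial nodes found")
        coords = mesh.node_coords[cand]
        z_apex, z_base = coords[:, 2].min(), coords[:, 2].max()
        z_target = z_apex + RV_SITE_HEIGHT[label] * (z_base - z_apex)
        # prefer nodes near the mid-coronal plane for determinism
        score = np.abs(coords[:, 2] - z_target) + 0.05 * np.abs(coords[:, 1])
        center_node = cand[int(np.argmin(score))]
        pool = cand
    else:
        parts = label.split("_")
        if (len(parts) != 4 or parts[0] != "LV" or parts[1] not in SEG_CIRC
                or parts[2] not in SEG_LONG or parts[3] not in ("EPI", "ENDO")):
            raise ValueError(f"unknown lead label: {label!r}")
        code = segment_code(parts[1], parts[2])
        tag = TAG_EPI if parts[3] == "EPI" else TAG_LV_ENDO
        elem_mask = mesh.region == code
        if not elem_mask.any():
            raise ValueError(f"mesh has no LV segment {parts[1]}_{parts[2]}; "
                             "run segment_lv_free_wall first")
        cand = _surface_nodes_of_elements(mesh, elem_mask, tag)
        if cand.size == 0:
            raise ValueError(f"segment {label} has no {parts[3]} surface nodes")
        centroid = mesh.node_coords[cand].mean(axis=0)
        d = np.linalg.norm(mesh.node_coords[cand] - centroid, axis=1)
        center_node = cand[int(np.argmin(d))]
        pool = cand

    center = mesh.node_coords[center_node]
    side = LEAD_CUBE_VOLUME_MM3 ** (1.0 / 3.0)
    inside = np.all(np.abs(mesh.node_coords[pool] - center) <= side / 2.0 + 1e-12,
                    axis=1)
    node_set = pool[inside]
    if node_set.size == 0:
        node_set = np.array([center_node])
    return LeadSite(label=label, center=center.copy(),
                    node_set=np.sort(node_set).astype(np.int64))


# ---------------------------------------------------------------------------
# mesh validity
# ---------------------------------------------------------------------------


def euler_characteristic(mesh: Mesh) -> int:
    """V - E + F - C of the voxel complex (1 for a solid ball)."""
    elems = mesh.hex_elements.astype(np.int64)
    V = mesh.n_nodes
    C = mesh.n_elements
    edge_pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7),
                  (7, 4), (0, 4), (1, 5), (2, 6), (3, 7)]
    edges = np.sort(elems[:, edge_pairs], axis=2).reshape(-1, 2)
    E = np.unique(edges, axis=0).shape[0]
    face_quads = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4), (2, 3, 7, 6),
                  (0, 3, 7, 4), (1, 2, 6, 5)]
    faces = np.sort(elems[:, face_quads], axis=2).reshape(-1, 4)
    F = np.unique(faces, axis=0).shape[0]
    return int(V - E + F - C)
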