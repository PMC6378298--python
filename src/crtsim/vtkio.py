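"""Text exports: legacy-ASCII VTK meshes/polylines, PMJ tables and run
manifests.  All outputs are plain text."""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .geometry import Mesh
from .purkinje import BRANCH_NAMES, PurkinjeTree


def write_vtk_mesh(path, mesh: Mesh, node_data: dict | None = None,
                   element_data: dict | None = None) -> None:
    """Hexahedral mesh as a legacy-ASCII VTK unstructured grid.

    Fiber directions, cell type and region labels ride along as cell
    data; surface tags (plus any user arrays) as point data.
    """
    element_data = {"celltype": mesh.celltype, "region": mesh.region,
                    **(element_data or {})}
    node_data = {"surface_tag": mesh.surface_tags, **(node_data or {})}
    E = mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncrtsim mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.node_coords, fmt="%.9g")
        fh.write(f"CELLS {E} {E * 9}\n")
        cells = np.column_stack([np.full(E, 8), mesh.hex_elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {E}\n")
        np.savetxt(fh, np.full(E, 12), fmt="%d")
        fh.write(f"CELL_DATA {E}\n")
        fh.write("VECTORS fiber double\n")
        np.savetxt(fh, mesh.fiber_dirs, fmt="%.9g")
        for name, arr in element_data.items():
            _scalar(fh, name, arr)
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in node_data.items():
            _scalar(fh, name, arr)


def _scalar(fh, name, arr):
    arr = np.asarray(arr)
    kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
    fmt = "%d" if kind == "int" else "%.9g"
    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    np.savetxt(fh, arr.reshape(-1, 1), fmt=fmt)


def write_vtk_tree(path, tree: PurkinjeTree) -> None:
    """Purkinje tree as VTK polylines with branch/block edge data and a
    PMJ marker on the nodes."""
    K = tree.edges.shape[0]
    is_pmj = np.zeros(tree.n_nodes, dtype=int)
    is_pmj[tree.pmj_nodes] = 1
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncrtsim purkinje tree\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {tree.n_nodes} double\n")
        np.savetxt(fh, tree.nodes, fmt="%.9g")
        fh.write(f"LINES {K} {K * 3}\n")
        np.savetxt(fh, np.column_stack([np.full(K, 2), tree.edges]), fmt="%d")
        fh.write(f"CELL_DATA {K}\n")
        _scalar(fh, "branch_label", tree.branch_label.astype(int))
        _scalar(fh, "blocked", tree.edge_blocked.astype(int))
        fh.write(f"POINT_DATA {tree.n_nodes}\n")
        _scalar(fh, "is_pmj", is_pmj)


def write_pmj_csv(path, tree: PurkinjeTree) -> None:
    """PMJ pairing table: tree node, myocardial node, both delays."""
    with open(path, "w") as fh:
        fh.write("tree_node,myo_node,delay_antero_ms,delay_retro_ms\n")
        for tn, mn in zip(tree.pmj_nodes, tree.pmj_myo_nodes):
            fh.write(f"{tn},{mn},{tree.pmj_delay_antero},"
                     f"{tree.pmj_delay_retro}\n")


def mesh_content_hash(mesh: Mesh) -> str:
    """Deterministic content hash of the mesh arrays (run provenance)."""
    hsh = hashlib.sha256()
    for arr in (mesh.node_coords, mesh.hex_elements, mesh.fiber_dirs,
                mesh.celltype, mesh.region, mesh.surface_tags):
        hsh.update(np.ascontiguousarray(arr).tobytes())
    return hsh.hexdigest()[:16]


def write_manifest(path, entries: dict) -> None:
    """Run manifest (parameters, seed, content hashes) as JSON text."""
    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v

    with open(path, "w") as fh:
        json.dump({k: _clean(v) for k, v in entries.items()}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
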