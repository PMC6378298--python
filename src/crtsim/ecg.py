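"""Forward ECG: precordial traces from tissue V_m via a pseudo-ECG.

The extracellular potential is approximated with the classical
unbounded homogeneous volume-conductor formula

    phi_e(x_e, t) = k * sum_elements  vol * (-D grad V_m) . (x_e - x) / r^3,

i.e. every element contributes a current dipole -D grad V_m; this is the
documented surrogate for a heterogeneous-torso bidomain solve (whose
organ-conductivity table is retained as config metadata).  Each
precordial lead is referenced against the mean potential of three distal
reference electrodes (Wilson-central-terminal surrogate).  The gain k is
arbitrary but fixed, so morphology and timing are meaningful while
absolute voltages are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ElectrodeLayout, Mesh, PRECORDIAL_LABELS
from .monodomain import ConductivityField, SimulationResult


@dataclass
class ECGTraces:
    """Six precordial leads on a shared time base (mV, arbitrary gain)."""

    times: np.ndarray           # (T,) ms
    leads: np.ndarray           # (6, T), ordered V1..V6
    reference: str = "WCT_SURROGATE"
    sample_rate_khz: float = 1.0

    def lead(self, label: str) -> np.ndarray:
        return self.leads[PRECORDIAL_LABELS.index(label)]

    def mean_trace(self) -> np.ndarray:
        return self.leads.mean(axis=0)

    def to_csv(self, path) -> None:
        header = "time_ms," + ",".join(PRECORDIAL_LABELS)
        data = np.column_stack([self.times, self.leads.T])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ECGTraces":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        times = data[:, 0]
        dt = np.median(np.diff(times)) if times.size > 1 else 1.0
        return cls(times=times, leads=data[:, 1:7].T,
                   sample_rate_khz=1.0 / dt)


def place_precordial(mesh: Mesh, standoff_mm: float = 40.0,
                     reference_distance_mm: float = 200.0) -> ElectrodeLayout:
    """Standard-ordered precordial layout on the anterior torso shell.

    The heart frame has the septum toward +x and the anterior wall toward
    +y, so V1 starts over the RV (+x) and V6 ends lateral to the LV (-x),
    all on a plane ``standoff_mm`` anterior to the mesh.  Three reference
    sites (two shoulders, one leg surrogate) sit ``reference_distance_mm``
    away.
    """
    if standoff_mm <= 0:
        raise ValueError("torso shell must enclose the mesh "
                         "(standoff must be positive)")
    lo = mesh.node_coords.min(axis=0)
    hi = mesh.node_coords.max(axis=0)
    c = 0.5 * (lo + hi)
    w = hi[0] - lo[0]
    y_front = hi[1] + standoff_mm
    xs = np.linspace(hi[0] + 0.25 * w, lo[0] - 0.25 * w, 6)
    zs = c[2] + np.linspace(0.15, -0.20, 6) * (hi[2] - lo[2])
    prec = np.column_stack([xs, np.full(6, y_front), zs])
    refs = np.array([
        [hi[0] + reference_distance_mm, c[1], hi[2] + reference_distance_mm / 2],
        [lo[0] - reference_distance_mm, c[1], hi[2] + reference_distance_mm / 2],
        [lo[0] - reference_distance_mm / 3, c[1], lo[2] - reference_distance_mm],
    ])
    return ElectrodeLayout(precordial_positions=prec,
                           reference_positions=refs)


def _gradient_operator(mesh: Mesh) -> sp.csr_matrix:
    """Sparse (3E, N) map from node values to element-centre gradients."""
    h = mesh.edge_length
    E = mesh.n_elements
    N = mesh.n_nodes
    elems = mesh.hex_elements
    # VTK corner ordering: +x corners (1,2,5,6); +y (2,3,6,7); +z (4,5,6,7)
    plus = {0: (1, 2, 5, 6), 1: (2, 3, 6, 7), 2: (4, 5, 6, 7)}
    rows, cols, vals = [], [], []
    for axis in range(3):
        for corner in range(8):
            sign = 1.0 if corner in plus[axis] else -1.0
            rows.append(np.arange(E) * 3 + axis)
            cols.append(elems[:, corner].astype(np.int64))
            vals.append(np.full(E, sign / (4.0 * h)))
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * E, N)).tocsr()


def electrode_lead_field(mesh: Mesh, cond: ConductivityField,
                         positions: np.ndarray, gain: float = 1.0
                         ) -> np.ndarray:
    """(n_electrodes, N) matrix W with phi_e(t) = W @ V(t)."""
    centers = mesh.element_centers()
    h = mesh.edge_length
    for p in positions:
        if np.min(np.linalg.norm(centers - p[None, :], axis=1)) < h:
            raise ValueError("electrode lies inside the myocardium")
    D = cond.tensors(mesh)                    # (E, 3, 3)
    G = _gradient_operator(mesh)              # (3E, N)
    vol = h ** 3
    W = np.empty((positions.shape[0], mesh.n_nodes))
    for k, p in enumerate(positions):
        rvec = p[None, :] - centers           # (E, 3)
        r3 = np.linalg.norm(rvec, axis=1) ** 3
        a = rvec / r3[:, None]                # grad_x (1/r)
        b = -gain * vol * np.einsum("eab,ea->eb", D, a)   # dot with -D grad V
        W[k] = G.T @ b.ravel()
    return W


def pseudo_ecg(result: SimulationResult, mesh: Mesh, cond: ConductivityField,
               layout: ElectrodeLayout, gain: float = 1.0) -> ECGTraces:
    """Precordial pseudo-ECG traces from the recorded V_m samples."""
    if result.V_m_samples is None:
        raise ValueError("simulation was run without V_m recording")
    if result.times.size > 1:
        sample_dt = float(np.median(np.diff(result.times)))
        if sample_dt > 1.0 + 1e-9:
            raise ValueError("V_m must be sampled at >= 1 kHz for the ECG")
    pos = np.vstack([layout.precordial_positions, layout.reference_positions])
    W = electrode_lead_field(mesh, cond, pos, gain=gain)
    V = result.V_m_samples.astype(np.float64)         # (T, N)
    phi = V @ W.T                                     # (T, 9)
    wct = phi[:, 6:9].mean(axis=1)
    leads = (phi[:, :6] - wct[:, None]).T
    sr = 1.0 / sample_dt if result.times.size > 1 else 1.0
    return ECGTraces(times=result.times.copy(), leads=leads,
                     sample_rate_khz=sr)
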