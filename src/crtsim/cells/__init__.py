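"""Cell-level electrophysiology: ventricular (ORd-family) and Purkinje
(Stewart) membrane models, parameter containers and pacing protocols."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ord as _ord
from . import stewart as _stewart
from .ord import (GNA_MODIFIED_FRACTION, GNA_ORIGINAL,
                  GNAL_MODIFIED_FACTOR, GNAL_ORIGINAL, ORD_STATE_NAMES,
                  ord_initial_state)
from .stewart import STEWART_STATE_NAMES, stewart_initial_state

CELLTYPE_CODES = {"ENDO": 0, "MID": 1, "EPI": 2, "PURKINJE": 3}


@dataclass(frozen=True)
class IonicModelParams:
    """Membrane-model selection and the conductances this study varies.

    ``gate_mod_flags`` switches the three I_Na gate modifications
    (m_ss, h_ss/j_ss, tau_h/tau_j) individually; the modified model has
    all three on, G_Na at 23% of the original 75 mS/uF and G_NaL doubled.
    ``C_m`` is the membrane capacitance in uF/cm^2 (the membrane models
    are normalised per capacitance, so it only scales stimulus bookkeeping).
    """

    model_id: str
    celltype: str
    G_Na: float
    G_NaL: float
    gate_mod_flags: tuple[bool, bool, bool] = (False, False, False)
    C_m: float = 1.0

    def __post_init__(self):
        if self.model_id not in ("ORD_MODIFIED", "ORD_ORIGINAL", "STEWART"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.celltype not in CELLTYPE_CODES:
            raise ValueError(f"unknown celltype {self.celltype!r}")
        if self.G_Na < 0 or self.G_NaL < 0:
            raise ValueError("conductances must be nonnegative")
        if self.model_id == "ORD_MODIFIED":
            if abs(self.G_Na - GNA_MODIFIED_FRACTION * GNA_ORIGINAL) > 1e-9:
                raise ValueError("ORD_MODIFIED requires G_Na = 23% of the "
                                 "original value")
            if abs(self.G_NaL - GNAL_MODIFIED_FACTOR * GNAL_ORIGINAL) > 1e-12:
                raise ValueError("ORD_MODIFIED requires doubled G_NaL")

    @property
    def celltype_code(self) -> int:
        return CELLTYPE_CODES[self.celltype]

    @classmethod
    def ord_modified(cls, celltype: str = "ENDO") -> "IonicModelParams":
        return cls("ORD_MODIFIED", celltype,
                   GNA_MODIFIED_FRACTION * GNA_ORIGINAL,
                   GNAL_MODIFIED_FACTOR * GNAL_ORIGINAL,
                   (True, True, True))

    @classmethod
    def ord_original(cls, celltype: str = "ENDO") -> "IonicModelParams":
        return cls("ORD_ORIGINAL", celltype, GNA_ORIGINAL, GNAL_ORIGINAL,
                   (False, False, False))

    @classmethod
    def stewart(cls) -> "IonicModelParams":
        return cls("STEWART", "PURKINJE", 130.5744, 0.0)


def state_for(params: IonicModelParams) -> np.ndarray:
    """Published initial state vector for the parameterised model."""
    if params.model_id == "STEWART":
        return stewart_initial_state()
    return ord_initial_state()


def _check_state(state: np.ndarray, names) -> None:
    state = np.asarray(state, dtype=float)
    if state.shape != (len(names),):
        raise ValueError(f"state must have {len(names)} entries, "
                         f"got {state.shape}")
    bad = ~np.isfinite(state)
    if bad.any():
        first = names[int(np.argmax(bad))]
        raise ValueError(f"non-finite state variable: {first}")


def ord_modified_rhs(state, params: IonicModelParams,
                     I_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the (possibly modified) ventricular model.

    ``I_stim`` is the depolarising stimulus in uA/uF.  Raises on
    non-finite state entries, naming the first offending variable.
    """
    if params.model_id not in ("ORD_MODIFIED", "ORD_ORIGINAL"):
        raise ValueError("params must select a ventricular (ORd) model")
    _check_state(state, ORD_STATE_NAMES)
    mss, hjss, tauhj = params.gate_mod_flags
    return _ord.ord_derivative(np.asarray(state, dtype=float),
                               params.celltype_code, float(I_stim),
                               mss, hjss, tauhj, params.G_Na, params.G_NaL)


def stewart_rhs(state, params: IonicModelParams,
                I_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the Purkinje membrane model."""
    if params.model_id != "STEWART":
        raise ValueError("params must select the STEWART model")
    _check_state(state, STEWART_STATE_NAMES)
    return _stewart.stewart_derivative(np.asarray(state, dtype=float),
                                       float(I_stim))


def quiescent_state(params: IonicModelParams, relax_ms: float = 20000.0,
                    dt: float = 0.05, polish: bool = True) -> np.ndarray:
    """Approximate unstimulated resting fixed point of a ventricular cell.

    Integrates without stimulus for ``relax_ms`` (the fast modes collapse
    onto the slow ion-concentration manifold), then optionally polishes
    with a Levenberg-Marquardt root solve of the full right-hand side.
    """
    if params.model_id not in ("ORD_MODIFIED", "ORD_ORIGINAL"):
        raise ValueError("quiescent_state applies to the ventricular models")
    S = state_for(params)[None, :].copy()
    ct = np.array([params.celltype_code])
    stim = np.zeros(1)
    mss, hjss, tauhj = params.gate_mod_flags
    for _ in range(int(round(relax_ms / dt))):
        _ord.ord_step(S, ct, stim, dt, mss, hjss, tauhj,
                      params.G_Na, params.G_NaL)
    s = S[0]
    if polish:
        from scipy.optimize import root
        sol = root(lambda x: ord_modified_rhs(x, params, 0.0), s,
                   method="lm", options={"xtol": 1e-14, "ftol": 1e-14})
        if np.all(np.isfinite(sol.x)):
            s = sol.x
    return s


from .pacing import APMetrics, pace_cell  # noqa: E402  (public re-export)

__all__ = [
    "IonicModelParams", "APMetrics", "pace_cell", "state_for",
    "ord_modified_rhs", "stewart_rhs", "quiescent_state", "ORD_STATE_NAMES",
    "STEWART_STATE_NAMES", "CELLTYPE_CODES", "ord_initial_state",
    "stewart_initial_state",
]
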