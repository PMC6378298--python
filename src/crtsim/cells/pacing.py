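"""Single-cell pacing protocols and action-potential metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import ord as _ord
from . import stewart as _stewart


@dataclass(frozen=True)
class APMetrics:
    """Shape metrics of the last paced action potential.

    ``dVdt_max`` in mV/ms, ``APD90`` in ms (time from maximum upstroke to
    90% repolarisation), ``V_rest``/``V_peak`` in mV.  ``captured`` is
    False when the stimulus failed to elicit an AP (metrics are NaN).
    """

    dVdt_max: float
    APD90: float
    V_rest: float
    V_peak: float
    captured: bool

    def as_dict(self) -> dict:
        return {"dVdt_max": self.dVdt_max, "APD90": self.APD90,
                "V_rest": self.V_rest, "V_peak": self.V_peak,
                "captured": self.captured}


def pace_cell(params, bcl: float, n_beats: int, stim_amp: float = 60.0,
              stim_dur: float = 1.0, dt: float = 0.005,
              record_dt: float = 0.1):
    """Pace a single cell to (approximate) steady state.

    Integrates ``n_beats`` cycles of length ``bcl`` ms with a depolarising
    stimulus of ``stim_amp`` uA/uF for ``stim_dur`` ms at each cycle
    start, then returns ``(times, v_trace, APMetrics)`` for the final
    beat.  The trace is decimated to ``record_dt``; dV/dt_max is measured
    on the undecimated step sequence.
    """
    from . import state_for  # late import to avoid cycle

    if not bcl > stim_dur > 0:
        raise ValueError("need bcl > stim_dur > 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")

    S = state_for(params)[None, :].copy()
    ct = np.array([params.celltype_code], dtype=np.int64)
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    rec_every = max(int(round(record_dt / dt)), 1)

    stim = np.zeros(1)
    is_ord = params.model_id in ("ORD_MODIFIED", "ORD_ORIGINAL")
    mss, hjss, tauhj = (params.gate_mod_flags if is_ord else (False,) * 3)

    def _step(amp):
        stim[0] = amp
        if is_ord:
            _ord.ord_step(S, ct, stim, dt, mss, hjss, tauhj,
                          params.G_Na, params.G_NaL)
        else:
            _stewart.stewart_step(S, stim, dt)

    # conditioning beats
    for _ in range(n_beats - 1):
        for k in range(steps_per_beat):
            _step(stim_amp if k < stim_steps else 0.0)

    # final beat: record
    n_rec = steps_per_beat // rec_every + 1
    times = np.empty(n_rec)
    vtrace = np.empty(n_rec)
    times[0] = 0.0
    vtrace[0] = S[0, 0]
    v_rest = S[0, 0]
    dvdt_max = -np.inf
    t_up = 0.0
    ir = 1
    v_prev = S[0, 0]
    for k in range(steps_per_beat):
        _step(stim_amp if k < stim_steps else 0.0)
        v = S[0, 0]
        dvdt = (v - v_prev) / dt
        if dvdt > dvdt_max:
            dvdt_max = dvdt
            t_up = (k + 1) * dt
        v_prev = v
        if (k + 1) % rec_every == 0 and ir < n_rec:
            times[ir] = (k + 1) * dt
            vtrace[ir] = v
            ir += 1
    times = times[:ir]
    vtrace = vtrace[:ir]

    v_peak = float(vtrace.max())
    captured = v_peak > 0.0 and dvdt_max > 10.0
    if not captured:
        return times, vtrace, APMetrics(np.nan, np.nan, float(v_rest),
                                        v_peak, False)
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    after = times > t_up
    below = after & (vtrace < v90)
    apd90 = float(times[below][0] - t_up) if below.any() else np.nan
    return times, vtrace, APMetrics(float(dvdt_max), apd90, float(v_rest),
                                    v_peak, True)
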