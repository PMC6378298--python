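"""Membrane-model tests: the modified ventricular model against an
independent transcription of the published equations, the Purkinje model's
automaticity, and single-cell pacing metrics."""

import numpy as np
import pytest

from _ord_reference import ord_reference_rhs
from crtsim.cells import (IonicModelParams, ORD_STATE_NAMES,
                          STEWART_STATE_NAMES, ord_initial_state,
                          ord_modified_rhs, pace_cell, quiescent_state,
                          state_for, stewart_initial_state, stewart_rhs)
from crtsim.cells.ord import GNA_ORIGINAL, ord_step
from crtsim.cells.stewart import stewart_step


class TestVentricularModel:
    def test_quiescent_state_is_a_fixed_point(self):
        p = IonicModelParams.ord_original("ENDO")
        s = quiescent_state(p, relax_ms=20000.0)
        dv = ord_modified_rhs(s, p, 0.0)[0]
        assert abs(dv) < 1e-6

    def test_modified_conductance_relationship(self):
        p = IonicModelParams.ord_modified()
        assert p.G_Na == pytest.approx(0.23 * GNA_ORIGINAL)
        assert p.G_NaL == pytest.approx(2.0 * 0.0075)
        with pytest.raises(ValueError):
            IonicModelParams("ORD_MODIFIED", "ENDO", GNA_ORIGINAL, 0.015,
                             (True, True, True))

    @pytest.mark.parametrize("celltype", ["ENDO", "MID", "EPI"])
    def test_original_model_matches_independent_transcription(self, celltype):
        """With all gate modifications off and original conductances, the
        right-hand side equals a from-scratch transcription of the
        published equations on randomized valid states."""
        p = IonicModelParams.ord_original(celltype)
        rng = np.random.default_rng(7)
        for _ in range(10):
            s = ord_initial_state()
            s[0] += rng.uniform(-30, 60)
            s[1:9] *= rng.uniform(0.8, 1.2, 8)
            s[9:40] = np.clip(s[9:40] * rng.uniform(0.5, 1.5, 31), 1e-6, 1.0)
            a = ord_modified_rhs(s, p, 0.0)
            b = ord_reference_rhs(s, celltype, 0.0)
            np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-12)

    def test_nonfinite_state_names_first_offender(self):
        p = IonicModelParams.ord_original()
        s = ord_initial_state()
        s[ORD_STATE_NAMES.index("cai")] = np.nan
        with pytest.raises(ValueError, match="cai"):
            ord_modified_rhs(s, p)

    def test_rush_larsen_agrees_with_forward_euler_gates(self):
        """One paced AP integrated with Rush-Larsen gates vs plain
        forward-Euler on the full derivative: within 0.5 mV pointwise.

        Uses the original model: the modified inactivation time
        constants fall below 1 us at depolarised potentials, where
        explicit Euler gating is unconditionally unstable (the reason
        the solver uses Rush-Larsen in the first place)."""
        p = IonicModelParams.ord_original("ENDO")
        dt = 0.005
        n = int(400 / dt)
        S = state_for(p)[None, :].copy()
        ct = np.array([0])
        stim = np.zeros(1)
        s_eu = state_for(p).copy()
        mss, hjss, tauhj = p.gate_mod_flags
        worst = 0.0
        for k in range(n):
            amp = 60.0 if k * dt < 1.0 else 0.0
            stim[0] = amp
            ord_step(S, ct, stim, dt, mss, hjss, tauhj, p.G_Na, p.G_NaL)
            s_eu += dt * ord_modified_rhs(s_eu, p, amp)
            if k % 40 == 0:
                worst = max(worst, abs(S[0, 0] - s_eu[0]))
        assert worst < 0.5

    def test_gna_cut_halves_clamp_peak_and_gnal_doubles(self):
        """Voltage clamp from -100 mV to -20 mV: the gate modifications
        plus the 23% sodium-conductance cut roughly halve the peak
        I_Na, which the doubled late-sodium conductance is there to
        compensate (the late current itself scales exactly with
        G_NaL)."""
        from crtsim.cells.ord import ord_sodium_currents

        def clamp_peak_late(p):
            s = state_for(p).copy()
            mss, hjss, tauhj = p.gate_mod_flags
            dt = 0.005
            s[0] = -100.0
            S = s[None, :].copy()
            stim = np.zeros(1)
            ct = np.array([0])
            for _ in range(int(50 / dt)):      # equilibrate at holding
                ord_step(S, ct, stim, dt, mss, hjss, tauhj, p.G_Na, p.G_NaL)
                S[0, 0] = -100.0
            peak = 0.0
            late = 0.0
            for k in range(int(100 / dt)):     # step to -20 mV
                S[0, 0] = -20.0
                ord_step(S, ct, stim, dt, mss, hjss, tauhj, p.G_Na, p.G_NaL)
                S[0, 0] = -20.0
                ina, inal = ord_sodium_currents(S[0], 0, mss, hjss, tauhj,
                                                p.G_Na, p.G_NaL)
                peak = min(peak, ina)
                if k * dt > 95.0:
                    late = inal
            return abs(peak), abs(late)

        pk_o, lt_o = clamp_peak_late(IonicModelParams.ord_original("ENDO"))
        pk_m, lt_m = clamp_peak_late(IonicModelParams.ord_modified("ENDO"))
        assert 0.3 < pk_m / pk_o < 0.7          # peak roughly halves
        assert lt_m / lt_o == pytest.approx(2.0, rel=0.25)


class TestPurkinjeModel:
    def test_spontaneous_automaticity(self):
        """An unstimulated Purkinje cell fires at least one AP within
        2000 ms (funny-current driven diastolic depolarisation)."""
        S = stewart_initial_state()[None, :].copy()
        stim = np.zeros(1)
        dt = 0.02
        crossings = 0
        prev = S[0, 0]
        gates_ok = True
        for k in range(int(2000 / dt)):
            stewart_step(S, stim, dt)
            v = S[0, 0]
            if prev < -20.0 <= v:
                crossings += 1
            prev = v
            if k * dt < 1000.0 and k % 500 == 0:
                g = S[0, 4:11]
                gates_ok &= bool(np.all((g >= 0) & (g <= 1)))
        assert crossings >= 1
        assert gates_ok

    def test_paced_peak_positive(self):
        p = IonicModelParams.stewart()
        _, v, m = pace_cell(p, 1000.0, 2, stim_amp=40.0, stim_dur=1.0,
                            dt=0.02)
        assert m.captured and m.V_peak > 0.0

    def test_nonfinite_state_rejected(self):
        s = stewart_initial_state()
        s[STEWART_STATE_NAMES.index("casr")] = np.inf
        with pytest.raises(ValueError, match="casr"):
            stewart_rhs(s, IonicModelParams.stewart())


class TestPacing:
    def test_no_stimulus_no_capture(self):
        p = IonicModelParams.ord_modified("ENDO")
        _, _, m = pace_cell(p, 500.0, 1, stim_amp=1e-9, stim_dur=0.5,
                            dt=0.01)
        assert not m.captured
        assert np.isnan(m.APD90)

    def test_upstroke_velocity_converges_in_dt(self):
        p = IonicModelParams.ord_modified("ENDO")
        _, _, m1 = pace_cell(p, 1000.0, 3, dt=0.005)
        _, _, m2 = pace_cell(p, 1000.0, 3, dt=0.0025)
        assert abs(m1.dVdt_max / m2.dVdt_max - 1.0) < 0.02

    def test_apd_reaches_steady_state(self):
        """Doubling the conditioning beats changes APD90 by < 2 ms."""
        p = IonicModelParams.ord_modified("ENDO")
        _, _, m1 = pace_cell(p, 1000.0, 50, dt=0.01)
        _, _, m2 = pace_cell(p, 1000.0, 100, dt=0.01)
        assert abs(m1.APD90 - m2.APD90) < 2.0

    def test_invalid_protocol_rejected(self):
        p = IonicModelParams.ord_modified("ENDO")
        with pytest.raises(ValueError):
            pace_cell(p, 1.0, 1, stim_dur=2.0)
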