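"""Purkinje-fibre action potential model (Stewart et al. 2009 formulation).

A ten Tusscher-Panfilov-family ventricular model extended with the
hyperpolarisation-activated funny current I_f and a sustained outward
current I_sus, and with a reduced inward rectifier; together these give
the cell intrinsic automaticity (slow diastolic depolarisation).

State layout (frozen):
v, ki, nai, cai, y, xr1, xr2, xs, m, h, j, cass, casr, rbar, d, f, f2,
fcass.

Units: mV, ms, mM, uA/uF.  Gating states use Rush-Larsen (the SR-release
gate rbar is linear in itself and is folded into the same scheme);
concentrations and voltage use forward Euler.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STEWART_STATE_NAMES = (
    "v", "ki", "nai", "cai", "y", "xr1", "xr2", "xs", "m", "h", "j",
    "cass", "casr", "rbar", "d", "f", "f2", "fcass", "s_to", "r_to",
)
N_STATES = len(STEWART_STATE_NAMES)
IDX_V = 0

# Rush-Larsen slots: y xr1 xr2 xs m h j rbar d f f2 fcass s_to r_to
_RL_IDX = np.array([4, 5, 6, 7, 8, 9, 10, 13, 14, 15, 16, 17, 18, 19])
_EU_IDX = np.array([0, 1, 2, 3, 11, 12])
_N_RL = 14

# published initial conditions
_STEWART_INIT = np.array([
    -69.1370441635924, 136.781894160227, 8.80420286531673,
    0.000101878186157052, 0.0457562667986602, 0.00550281999719088,
    0.313213286437995, 0.00953708522974789, 0.0417391656294997,
    0.190678733735145, 0.238219836154029, 0.000446818714055411,
    3.10836886659417, 0.991580051907845, 0.000287906256206415,
    0.989328560287987, 0.995474890442185, 0.999955429598213,
    0.963861017995497, 0.00103618091196912,
])


def stewart_initial_state() -> np.ndarray:
    return _STEWART_INIT.copy()


@njit(cache=True)
def stewart_rates(s, istim, deriv, rl_inf, rl_tau):
    """Right-hand side for one Purkinje cell (see module docstring)."""
    R = 8314.472
    T = 310.0
    F = 96485.3415
    Cm = 0.185          # uF
    V_c = 0.016404      # um^3 (scaled)
    V_sr = 0.001094
    V_ss = 0.00005468
    Ko = 5.4
    Nao = 140.0
    Cao = 2.0

    g_Na = 130.5744
    g_K1 = 0.065
    g_Kr = 0.0918
    g_Ks = 0.2352
    g_CaL = 3.98e-5
    g_bna = 0.00029
    g_bca = 0.000592
    g_to = 0.08184
    g_sus = 0.0227
    g_f_Na = 0.0145654
    g_f_K = 0.0234346
    P_NaK = 2.724
    K_mk = 1.0
    K_mNa = 40.0
    K_NaCa = 1000.0
    K_sat = 0.1
    alpha_ncx = 2.5
    gamma_ncx = 0.35
    Km_Ca = 1.38
    Km_Nai = 87.5
    g_pCa = 0.1238
    K_pCa = 0.0005
    g_pK = 0.0146
    P_kna = 0.03

    v = s[0]
    ki = s[1]
    nai = s[2]
    cai = s[3]
    y = s[4]
    xr1 = s[5]
    xr2 = s[6]
    xs = s[7]
    m = s[8]
    h = s[9]
    j = s[10]
    cass = s[11]
    casr = s[12]
    rbar = s[13]
    d = s[14]
    f = s[15]
    f2 = s[16]
    fcass = s[17]
    s_to = s[18]
    r_to = s[19]

    E_Na = (R * T / F) * np.log(Nao / nai)
    E_K = (R * T / F) * np.log(Ko / ki)
    E_Ks = (R * T / F) * np.log((Ko + P_kna * Nao) / (ki + P_kna * nai))
    E_Ca = 0.5 * (R * T / F) * np.log(Cao / cai)

    # funny current
    y_inf = 1.0 / (1.0 + np.exp((v + 80.6) / 6.8))
    alpha_y = np.exp(-2.9 - 0.04 * v)
    beta_y = np.exp(3.6 + 0.11 * v)
    tau_y = 4000.0 / (alpha_y + beta_y)
    i_f_Na = y * g_f_Na * (v - E_Na)
    i_f_K = y * g_f_K * (v - E_K)

    # sustained outward
    a_sus = 1.0 / (1.0 + np.exp((5.0 - v) / 17.0))
    i_sus = g_sus * a_sus * (v - E_K)

    # transient outward
    s_inf = 1.0 / (1.0 + np.exp((v + 27.0) / 13.0))
    tau_s = (85.0 * np.exp(-((v + 25.0) ** 2) / 320.0)
             + 5.0 / (1.0 + np.exp((v - 40.0) / 5.0)) + 42.0)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 13.0))
    tau_r = 10.45 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 7.3
    i_to = g_to * r_to * s_to * (v - E_K)

    # inward rectifier (reduced, shifted)
    xK1_inf = 1.0 / (1.0 + np.exp(0.1 * (v + 75.44)))
    i_K1 = g_K1 * xK1_inf * (v - 8.0 - E_K)

    # rapid delayed rectifier
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1
    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2
    i_Kr = g_Kr * np.sqrt(Ko / 5.4) * xr1 * xr2 * (v - E_K)

    # slow delayed rectifier
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0
    i_Ks = g_Ks * xs * xs * (v - E_Ks)

    # fast sodium
    m_inf = 1.0 / ((1.0 + np.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tau_m = am * bm
    h_inf = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 310000.0 * np.exp(0.3485 * v)
    tau_h = 1.0 / (ah + bh)
    j_inf = h_inf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-25428.0 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
              * (v + 37.78)) / (1.0 + np.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tau_j = 1.0 / (aj + bj)
    i_Na = g_Na * m ** 3 * h * j * (v - E_Na)

    # L-type calcium
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + gd
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
              + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    vm15 = v - 15.0
    x = 2.0 * vm15 * F / (R * T)
    if abs(x) > 1e-7:
        i_CaL = g_CaL * d * f * f2 * fcass * 4.0 * vm15 * (F * F / (R * T)) \
            * (0.25 * cass * np.exp(x) - Cao) / (np.exp(x) - 1.0)
    else:
        i_CaL = g_CaL * d * f * f2 * fcass * 2.0 * F * (0.25 * cass - Cao)

    # exchanger / pumps / background
    efv = np.exp(gamma_ncx * v * F / (R * T))
    efv1 = np.exp((gamma_ncx - 1.0) * v * F / (R * T))
    i_NaCa = K_NaCa * (efv * nai ** 3 * Cao - efv1 * Nao ** 3 * cai * alpha_ncx) \
        / ((Km_Nai ** 3 + Nao ** 3) * (Km_Ca + Cao) * (1.0 + K_sat * efv1))
    i_NaK = P_NaK * Ko * nai / ((Ko + K_mk) * (nai + K_mNa)
                                * (1.0 + 0.1245 * np.exp(-0.1 * v * F / (R * T))
                                   + 0.0353 * np.exp(-v * F / (R * T))))
    i_pCa = g_pCa * cai / (cai + K_pCa)
    i_pK = g_pK * (v - E_K) / (1.0 + np.exp((25.0 - v) / 5.98))
    i_b_Na = g_bna * (v - E_Na)
    i_b_Ca = g_bca * (v - E_Ca)

    # calcium handling
    Vmax_up = 0.006375
    K_up = 0.00025
    i_up = Vmax_up / (1.0 + (K_up * K_up) / (cai * cai))
    V_leak = 0.00036
    i_leak = V_leak * (casr - cai)
    V_xfer = 0.0038
    i_xfer = V_xfer * (cass - cai)
    k1p = 0.15
    k2p = 0.045
    k3 = 0.060
    k4 = 0.005
    EC = 1.5
    max_sr = 2.5
    min_sr = 1.0
    kcasr = max_sr - (max_sr - min_sr) / (1.0 + (EC / casr) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    O = k1 * cass * cass * rbar / (k3 + k1 * cass * cass)
    V_rel = 0.102
    i_rel = V_rel * O * (casr - cass)
    # rbar: d(rbar)/dt = -k2*cass*rbar + k4*(1-rbar)  (linear -> RL form)
    tau_rbar = 1.0 / (k2 * cass + k4)
    rbar_inf = k4 * tau_rbar

    Buf_c = 0.2
    K_buf_c = 0.001
    Buf_sr = 10.0
    K_buf_sr = 0.3
    Buf_ss = 0.4
    K_buf_ss = 0.00025
    Bcai = 1.0 / (1.0 + Buf_c * K_buf_c / ((cai + K_buf_c) ** 2))
    Bcasr = 1.0 / (1.0 + Buf_sr * K_buf_sr / ((casr + K_buf_sr) ** 2))
    Bcass = 1.0 / (1.0 + Buf_ss * K_buf_ss / ((cass + K_buf_ss) ** 2))

    Itot = (i_K1 + i_to + i_Kr + i_Ks + i_CaL + i_NaK + i_Na + i_b_Na
            + i_NaCa + i_b_Ca + i_pK + i_pCa + i_f_Na + i_f_K + i_sus
            - istim)

    deriv[0] = -Itot
    deriv[1] = -(i_K1 + i_to + i_f_K + i_sus + i_Kr + i_Ks + i_pK
                 - 2.0 * i_NaK - istim) * Cm / (V_c * F)
    deriv[2] = -(i_Na + i_b_Na + i_f_Na + 3.0 * i_NaK + 3.0 * i_NaCa) \
        * Cm / (V_c * F)
    deriv[3] = Bcai * ((i_leak - i_up) * V_sr / V_c + i_xfer
                       - (i_b_Ca + i_pCa - 2.0 * i_NaCa) * Cm / (2.0 * V_c * F))
    deriv[11] = Bcass * (-i_CaL * Cm / (2.0 * V_ss * F)
                         + i_rel * V_sr / V_ss - i_xfer * V_c / V_ss)
    deriv[12] = Bcasr * (i_up - i_rel - i_leak)

    rl_inf[0] = y_inf
    rl_tau[0] = tau_y
    rl_inf[1] = xr1_inf
    rl_tau[1] = tau_xr1
    rl_inf[2] = xr2_inf
    rl_tau[2] = tau_xr2
    rl_inf[3] = xs_inf
    rl_tau[3] = tau_xs
    rl_inf[4] = m_inf
    rl_tau[4] = tau_m
    rl_inf[5] = h_inf
    rl_tau[5] = tau_h
    rl_inf[6] = j_inf
    rl_tau[6] = tau_j
    rl_inf[7] = rbar_inf
    rl_tau[7] = tau_rbar
    rl_inf[8] = d_inf
    rl_tau[8] = tau_d
    rl_inf[9] = f_inf
    rl_tau[9] = tau_f
    rl_inf[10] = f2_inf
    rl_tau[10] = tau_f2
    rl_inf[11] = fcass_inf
    rl_tau[11] = tau_fcass
    rl_inf[12] = s_inf
    rl_tau[12] = tau_s
    rl_inf[13] = r_inf
    rl_tau[13] = tau_r


@njit(cache=True)
def stewart_step(S, istim, dt):
    """Advance all Purkinje cells in ``S`` (n, 18) by one step."""
    n = S.shape[0]
    deriv = np.zeros(N_STATES)
    rl_inf = np.empty(_N_RL)
    rl_tau = np.empty(_N_RL)
    for c in range(n):
        s = S[c]
        stewart_rates(s, istim[c], deriv, rl_inf, rl_tau)
        for e in range(_EU_IDX.shape[0]):
            idx = _EU_IDX[e]
            s[idx] += dt * deriv[idx]
        for g in range(_N_RL):
            idx = _RL_IDX[g]
            s[idx] = rl_inf[g] + (s[idx] - rl_inf[g]) * np.exp(-dt / rl_tau[g])


@njit(cache=True)
def stewart_derivative(s, istim):
    deriv = np.zeros(N_STATES)
    rl_inf = np.empty(_N_RL)
    rl_tau = np.empty(_N_RL)
    stewart_rates(s, istim, deriv, rl_inf, rl_tau)
    for g in range(_N_RL):
        idx = _RL_IDX[g]
        deriv[idx] = (rl_inf[g] - s[idx]) / rl_tau[g]
    return deriv
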