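"""Human ventricular myocyte model (O'Hara-Rudy dynamic, 2011 formulation)
with the fast-sodium-current modifications used for tissue-scale conduction.

The baseline equations are a direct transcription of the published ORd
model (endo / mid / epi variants).  Four modifications, each individually
switchable, adapt I_Na for realistic propagation in coarse 3D tissue:

* ``mod_mss``    - steady-state activation m_ss replaced by the ten
                   Tusscher-type sigmoid (squared), per Mora et al.
* ``mod_hjss``   - steady-state inactivation h_ss = j_ss replaced by the
                   shifted sigmoid 1/(1+exp((V+78.5)/6.22)), per Passini
                   et al. (phosphorylated variant shifted by -6.2 mV).
* ``mod_tauhj``  - inactivation time constants tau_hfast and tau_j per
                   Dutta et al.
* G_Na scaled to 23% of the original 75 mS/uF and G_NaL doubled, which
  restores the ~260 mV/ms maximum upstroke velocity of the original
  model while preserving the I_NaL / peak I_Na relationship.

State layout (frozen; index = position in the state vector):
v, nai, nass, ki, kss, cai, cass, cansr, cajsr, m, hf, hs, j, hsp, jp,
mL, hL, hLp, a, iF, iS, ap, iFp, iSp, d, ff, fs, fcaf, fcas, jca, nca,
ffp, fcafp, xrf, xrs, xs1, xs2, xk1, Jrelnp, Jrelp, CaMKt.

Units: mV, ms, mM, uA/uF, mS/uF.  Gates are integrated with Rush-Larsen,
everything else with forward Euler.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ORD_STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(ORD_STATE_NAMES)
IDX_V = 0
_N_RL = 31           # states 9..39 use Rush-Larsen
_RL0 = 9

GNA_ORIGINAL = 75.0          # mS/uF
GNAL_ORIGINAL = 0.0075       # mS/uF (endo base; epi scaled by 0.6 in-model)
GNA_MODIFIED_FRACTION = 0.23
GNAL_MODIFIED_FACTOR = 2.0

# published steady-state initial values (1 Hz pacing, endocardial variant)
_ORD_INIT = np.array([
    -87.5, 7.268, 7.268, 144.65, 144.65, 8.6e-5, 8.49e-5, 1.61, 1.56,
    0.0074621, 0.692591, 0.692574, 0.692477, 0.448501, 0.692413,
    0.000194015, 0.496116, 0.265885,
    0.00101185, 0.999542, 0.589579, 0.000515567, 0.999542, 0.641861,
    2.43015e-9, 1.0, 0.910671, 1.0, 0.99982, 0.999977, 0.00267171, 1.0, 1.0,
    8.26608e-6, 0.453268, 0.270492, 0.0001963, 0.996801,
    2.53943e-5, 3.17262e-7, 0.0124065,
])


def ord_initial_state() -> np.ndarray:
    """Published resting initial conditions (copy)."""
    return _ORD_INIT.copy()


@njit(cache=True)
def ord_rates(s, celltype, mod_mss, mod_hjss, mod_tauhj, gna, gnal,
              istim, deriv, rl_inf, rl_tau, currents):
    """Right-hand side of the ORd model for one cell.

    Writes forward-Euler derivatives into ``deriv`` (Rush-Larsen slots
    zeroed) and gate targets/time-constants into ``rl_inf`` / ``rl_tau``
    for states 9..39.  ``celltype``: 0 endo, 1 mid, 2 epi.  ``currents``
    receives (INa, INaL, ICaL, Ito) for diagnostics.
    """
    R = 8314.0
    T = 310.0
    F = 96485.0
    nao = 140.0
    cao = 1.8
    ko = 5.4

    # cell geometry (cm, uF)
    L = 0.01
    rad = 0.0011
    pi = 3.14159265358979
    vcell = 1000.0 * pi * rad * rad * L
    Ageo = 2.0 * pi * rad * rad + 2.0 * pi * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    v = s[0]
    nai = s[1]
    nass = s[2]
    ki = s[3]
    kss = s[4]
    cai = s[5]
    cass = s[6]
    cansr = s[7]
    cajsr = s[8]
    m = s[9]
    hf = s[10]
    hs = s[11]
    j = s[12]
    hsp = s[13]
    jp = s[14]
    mL = s[15]
    hL = s[16]
    hLp = s[17]
    a = s[18]
    iF = s[19]
    iS = s[20]
    ap = s[21]
    iFp = s[22]
    iSp = s[23]
    d = s[24]
    ff = s[25]
    fs = s[26]
    fcaf = s[27]
    fcas = s[28]
    jca = s[29]
    nca = s[30]
    ffp = s[31]
    fcafp = s[32]
    xrf = s[33]
    xrs = s[34]
    xs1 = s[35]
    xs2 = s[36]
    xk1 = s[37]
    Jrelnp = s[38]
    Jrelp = s[39]
    CaMKt = s[40]

    ENa = (R * T / F) * np.log(nao / nai)
    EK = (R * T / F) * np.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * np.log((ko + PKNa * nao) / (ki + PKNa * nai))
    vfrt = v * F / (R * T)
    vffrt = v * F * F / (R * T)

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dCaMKt = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fp = 1.0 / (1.0 + KmCaMK / CaMKa)   # fraction of phosphorylated channels

    # ---------------- INa ----------------
    if mod_mss:
        mss = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03))
        mss = mss * mss
    else:
        mss = 1.0 / (1.0 + np.exp((-(v + 39.57)) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    if mod_hjss:
        hss = 1.0 / (1.0 + np.exp((v + 78.5) / 6.22))
        hssp = 1.0 / (1.0 + np.exp((v + 78.5 + 6.2) / 6.22))
    else:
        hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
        hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    if mod_tauhj:
        thf = 1.0 / (3.686e-6 * np.exp(-(v + 3.8875) / 7.8579)
                     + 16.0 * np.exp((v - 0.4963) / 9.1843))
    else:
        thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                     + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    if mod_tauhj:
        tj = 4.8590 + 1.0 / (0.8628 * np.exp(-(v + 116.7258) / 7.6005)
                             + 1.1096 * np.exp((v + 6.2719) / 9.0358))
    else:
        tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                            + 0.3052 * np.exp((v + 0.9941) / 38.45))
    thsp = 3.0 * ths
    tjp = 1.46 * tj
    hp = Ahf * hf + Ahs * hsp
    INa = gna * (v - ENa) * m ** 3 * ((1.0 - fp) * h * j + fp * hp * jp)

    # ---------------- INaL ----------------
    mLss = 1.0 / (1.0 + np.exp((-(v + 42.85)) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = gnal
    if celltype == 2:
        GNaL = GNaL * 0.6
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp) * hL + fp * hLp)

    # ---------------- Ito ----------------
    ass = 1.0 / (1.0 + np.exp((-(v - 14.34)) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    if celltype == 2:
        delta_epi = 1.0 - (0.95 / (1.0 + np.exp((v + 70.0) / 5.0)))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * np.exp((-(v + 100.0)) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp((-(v + 96.52)) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    tiF = tiF * delta_epi
    tiS = tiS * delta_epi
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + np.exp((-(v - 24.34)) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02
    if celltype == 1 or celltype == 2:
        Gto = Gto * 4.0
    Ito = Gto * (v - EK) * ((1.0 - fp) * a * i_gate + fp * ap * ip)

    # ---------------- ICaL / ICaNa / ICaK ----------------
    dss = 1.0 / (1.0 + np.exp((-(v + 3.940)) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    ktaup = 2.5
    tffp = ktaup * tff
    f_p = Aff * ffp + Afs * fs
    tfcafp = ktaup * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4.0)
    # nca integrated as a Rush-Larsen state: inf = anca*k2n/km2n, tau = 1/km2n
    e2v = np.exp(2.0 * vfrt)
    e1v = np.exp(vfrt)
    # driving-force terms guarded against the v -> 0 singularity
    if abs(vfrt) > 1e-7:
        PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * cao) / (e2v - 1.0)
        PhiCaNa = 1.0 * vffrt * (0.75 * nass * e1v - 0.75 * nao) / (e1v - 1.0)
        PhiCaK = 1.0 * vffrt * (0.75 * kss * e1v - 0.75 * ko) / (e1v - 1.0)
    else:
        PhiCaL = 2.0 * F * (cass - 0.341 * cao)
        PhiCaNa = F * (0.75 * nass - 0.75 * nao)
        PhiCaK = F * (0.75 * kss - 0.75 * ko)
    PCa = 0.0001
    if celltype == 1:
        PCa = PCa * 2.5
    elif celltype == 2:
        PCa = PCa * 1.2
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    ICaL = (1.0 - fp) * PCa * PhiCaL * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fp * PCap * PhiCaL * d * (f_p * (1.0 - nca) + jca * fcap * nca)
    ICaNa = (1.0 - fp) * PCaNa * PhiCaNa * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fp * PCaNap * PhiCaNa * d * (f_p * (1.0 - nca) + jca * fcap * nca)
    ICaK = (1.0 - fp) * PCaK * PhiCaK * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fp * PCaKp * PhiCaK * d * (f_p * (1.0 - nca) + jca * fcap * nca)

    # ---------------- IKr ----------------
    xrss = 1.0 / (1.0 + np.exp((-(v + 8.337)) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp((-(v - 47.78)) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp((-(v - 29.74)) / 25.94))
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046
    if celltype == 1:
        GKr = GKr * 0.8
    elif celltype == 2:
        GKr = GKr * 1.3
    IKr = GKr * np.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # ---------------- IKs ----------------
    xs1ss = 1.0 / (1.0 + np.exp((-(v + 11.60)) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp((-(v + 210.0)) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp((-(v + 66.54)) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034
    if celltype == 2:
        GKs = GKs * 1.4
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # ---------------- IK1 ----------------
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * ko + 144.59)
                                / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (np.exp((-(v + 127.2)) / 20.36)
                    + np.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908
    if celltype == 1:
        GK1 = GK1 * 1.3
    elif celltype == 2:
        GK1 = GK1 * 1.2
    IK1 = GK1 * np.sqrt(ko) * rk1 * xk1 * (v - EK)

    # ---------------- INaCa ----------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)

    # intracellular-compartment exchanger
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2.0)
    zna = 1.0
    zca = 2.0
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008
    if celltype == 1:
        Gncx = Gncx * 1.4
    elif celltype == 2:
        Gncx = Gncx * 1.1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace exchanger (same scheme with nass / cass)
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # ---------------- INaK ----------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3pna = 1899.0
    k3m = 79300.0
    k4pna = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * np.exp(delta * vfrt / 3.0)
    Knao = Knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3.0) / ((1.0 + nai / Knai) ** 3.0
                                        + (1.0 + ki / Kki) ** 2.0 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3.0) / ((1.0 + nao / Knao) ** 3.0
                                        + (1.0 + ko / Kko) ** 2.0 - 1.0)
    a3 = (k3pna * (ko / Kko) ** 2.0) / ((1.0 + nao / Knao) ** 3.0
                                        + (1.0 + ko / Kko) ** 2.0 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4pna * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2.0) / ((1.0 + nai / Knai) ** 3.0
                                      + (1.0 + ki / Kki) ** 2.0 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if celltype == 1:
        Pnak = Pnak * 0.7
    elif celltype == 2:
        Pnak = Pnak * 0.9
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # ---------------- background / pump ----------------
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if celltype == 2:
        GKb = GKb * 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    PCab = 2.5e-8
    if abs(vfrt) > 1e-7:
        INab = PNab * vffrt * (nai * e1v - nao) / (e1v - 1.0)
        ICab = PCab * 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    else:
        INab = PNab * F * (nai - nao)
        ICab = PCab * 2.0 * F * (cai - 0.341 * cao)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # ---------------- fluxes ----------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    if celltype == 1:
        Jrel_inf = Jrel_inf * 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    if celltype == 1:
        Jrel_infp = Jrel_infp * 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fp) * Jrelnp + fp * Jrelp

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if celltype == 2:
        Jupnp = Jupnp * 1.3
        Jupp = Jupp * 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp) * Jupnp + fp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ---------------- buffers & balances ----------------
    cmdnmax = 0.05
    if celltype == 2:
        cmdnmax = cmdnmax * 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab - istim)

    deriv[0] = -Itot
    deriv[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                * Acap / (F * vmyo) + JdiffNa * vss / vmyo)
    deriv[2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    deriv[3] = (-(Ito + IKr + IKs + IK1 + IKb - istim - 2.0 * INaK)
                * Acap / (F * vmyo) + JdiffK * vss / vmyo)
    deriv[4] = -ICaK * Acap / (F * vss) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2.0
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2.0)
    deriv[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
                       - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2.0
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2.0)
    deriv[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss)
                        + Jrel * vjsr / vss - Jdiff)
    deriv[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2.0)
    deriv[8] = Bcajsr * (Jtr - Jrel)
    for idx in range(_RL0, _RL0 + _N_RL):
        deriv[idx] = 0.0
    deriv[40] = dCaMKt

    # Rush-Larsen targets (index - 9)
    rl_inf[0] = mss
    rl_tau[0] = tm
    rl_inf[1] = hss
    rl_tau[1] = thf
    rl_inf[2] = hss
    rl_tau[2] = ths
    rl_inf[3] = jss
    rl_tau[3] = tj
    rl_inf[4] = hssp
    rl_tau[4] = thsp
    rl_inf[5] = jss
    rl_tau[5] = tjp
    rl_inf[6] = mLss
    rl_tau[6] = tmL
    rl_inf[7] = hLss
    rl_tau[7] = thL
    rl_inf[8] = hLssp
    rl_tau[8] = thLp
    rl_inf[9] = ass
    rl_tau[9] = ta
    rl_inf[10] = iss
    rl_tau[10] = tiF
    rl_inf[11] = iss
    rl_tau[11] = tiS
    rl_inf[12] = assp
    rl_tau[12] = ta
    rl_inf[13] = iss
    rl_tau[13] = tiFp
    rl_inf[14] = iss
    rl_tau[14] = tiSp
    rl_inf[15] = dss
    rl_tau[15] = td
    rl_inf[16] = fss
    rl_tau[16] = tff
    rl_inf[17] = fss
    rl_tau[17] = tfs
    rl_inf[18] = fcass
    rl_tau[18] = tfcaf
    rl_inf[19] = fcass
    rl_tau[19] = tfcas
    rl_inf[20] = fcass
    rl_tau[20] = tjca
    rl_inf[21] = anca * k2n / km2n
    rl_tau[21] = 1.0 / km2n
    rl_inf[22] = fss
    rl_tau[22] = tffp
    rl_inf[23] = fcass
    rl_tau[23] = tfcafp
    rl_inf[24] = xrss
    rl_tau[24] = txrf
    rl_inf[25] = xrss
    rl_tau[25] = txrs
    rl_inf[26] = xs1ss
    rl_tau[26] = txs1
    rl_inf[27] = xs2ss
    rl_tau[27] = txs2
    rl_inf[28] = xk1ss
    rl_tau[28] = txk1
    rl_inf[29] = Jrel_inf
    rl_tau[29] = tau_rel
    rl_inf[30] = Jrel_infp
    rl_tau[30] = tau_relp

    currents[0] = INa
    currents[1] = INaL
    currents[2] = ICaL
    currents[3] = Ito


@njit(cache=True)
def ord_step(S, celltype, istim, dt, mod_mss, mod_hjss, mod_tauhj, gna, gnal):
    """Advance all cells in ``S`` (n, 41) one step of length ``dt`` (ms).

    Rush-Larsen for gating states, forward Euler otherwise.  ``istim`` is
    the depolarising stimulus per cell in uA/uF.
    """
    n = S.shape[0]
    deriv = np.empty(N_STATES)
    rl_inf = np.empty(_N_RL)
    rl_tau = np.empty(_N_RL)
    cur = np.empty(4)
    for c in range(n):
        s = S[c]
        ord_rates(s, celltype[c], mod_mss, mod_hjss, mod_tauhj, gna, gnal,
                  istim[c], deriv, rl_inf, rl_tau, cur)
        for idx in range(_RL0):
            s[idx] += dt * deriv[idx]
        for g in range(_N_RL):
            idx = _RL0 + g
            s[idx] = rl_inf[g] + (s[idx] - rl_inf[g]) * np.exp(-dt / rl_tau[g])
        s[40] += dt * deriv[40]


@njit(cache=True)
def ord_derivative(s, celltype, istim, mod_mss, mod_hjss, mod_tauhj,
                   gna, gnal):
    """Full time-derivative vector ds/dt (Rush-Larsen slots converted)."""
    deriv = np.empty(N_STATES)
    rl_inf = np.empty(_N_RL)
    rl_tau = np.empty(_N_RL)
    cur = np.empty(4)
    ord_rates(s, celltype, mod_mss, mod_hjss, mod_tauhj, gna, gnal, istim,
              deriv, rl_inf, rl_tau, cur)
    for g in range(_N_RL):
        deriv[_RL0 + g] = (rl_inf[g] - s[_RL0 + g]) / rl_tau[g]
    return deriv


@njit(cache=True)
def ord_sodium_currents(s, celltype, mod_mss, mod_hjss, mod_tauhj, gna, gnal):
    """(I_Na, I_NaL) at the given state, for voltage-clamp diagnostics."""
    deriv = np.empty(N_STATES)
    rl_inf = np.empty(_N_RL)
    rl_tau = np.empty(_N_RL)
    cur = np.empty(4)
    ord_rates(s, celltype, mod_mss, mod_hjss, mod_tauhj, gna, gnal, 0.0,
              deriv, rl_inf, rl_tau, cur)
    return cur[0], cur[1]
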