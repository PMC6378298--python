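"""Independent reference transcription of the original O'Hara-Rudy
dynamic human ventricular model, used only as a test oracle.

Written as a direct, equation-by-equation numpy translation of the
published model (dictionary state, no Rush-Larsen factoring, no numba)
so that it shares no code with the implementation under test.
"""

import numpy as np

NAMES = ("v nai nass ki kss cai cass cansr cajsr m hf hs j hsp jp mL hL "
         "hLp a iF iS ap iFp iSp d ff fs fcaf fcas jca nca ffp fcafp xrf "
         "xrs xs1 xs2 xk1 Jrelnp Jrelp CaMKt").split()


def ord_reference_rhs(state_vec, celltype="ENDO", istim=0.0):
    """dstate/dt of the original published model (no modifications)."""
    s = dict(zip(NAMES, np.asarray(state_vec, dtype=float)))
    epi = celltype == "EPI"
    mid = celltype == "MID"

    R, T, F = 8314.0, 310.0, 96485.0
    nao, cao, ko = 140.0, 1.8, 5.4
    L, rad = 0.01, 0.0011
    vcell = 1000.0 * np.pi * rad * rad * L
    Ageo = 2 * np.pi * rad * rad + 2 * np.pi * rad * L
    Acap = 2 * Ageo
    vmyo, vnsr, vjsr, vss = (0.68 * vcell, 0.0552 * vcell, 0.0048 * vcell,
                             0.02 * vcell)

    v = s["v"]
    vfrt = v * F / (R * T)
    vffrt = v * F * F / (R * T)
    ENa = R * T / F * np.log(nao / s["nai"])
    EK = R * T / F * np.log(ko / s["ki"])
    EKs = R * T / F * np.log((ko + 0.01833 * nao)
                             / (s["ki"] + 0.01833 * s["nai"]))

    # CaMK
    CaMKb = 0.05 * (1.0 - s["CaMKt"]) / (1.0 + 0.0015 / s["cass"])
    CaMKa = CaMKb + s["CaMKt"]
    dCaMKt = 0.05 * CaMKb * (CaMKb + s["CaMKt"]) - 0.00068 * s["CaMKt"]
    phi = 1.0 / (1.0 + 0.15 / CaMKa)

    d = {}

    def gate(name, xinf, tau):
        d[name] = (xinf - s[name]) / tau

    # INa
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    gate("m", mss, tm)
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                 + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    gate("hf", hss, thf)
    gate("hs", hss, ths)
    h = 0.99 * s["hf"] + 0.01 * s["hs"]
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    gate("j", jss, tj)
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    gate("hsp", hssp, 3.0 * ths)
    gate("jp", jss, 1.46 * tj)
    hp = 0.99 * s["hf"] + 0.01 * s["hsp"]
    GNa = 75.0
    INa = GNa * (v - ENa) * s["m"] ** 3 * ((1.0 - phi) * h * s["j"]
                                           + phi * hp * s["jp"])

    # INaL
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    gate("mL", mLss, tm)
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    gate("hL", hLss, 200.0)
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    gate("hLp", hLssp, 600.0)
    GNaL = 0.0075 * (0.6 if epi else 1.0)
    INaL = GNaL * (v - ENa) * s["mL"] * ((1.0 - phi) * s["hL"]
                                         + phi * s["hLp"])

    # Ito
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    gate("a", ass, ta)
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    depi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0)) if epi else 1.0
    tiF = (4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                          + 0.08004 * np.exp((v + 50.0) / 16.59))) * depi
    tiS = (23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                          + 1.780e-8 * np.exp((v + 114.1) / 8.079))) * depi
    gate("iF", iss, tiF)
    gate("iS", iss, tiS)
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    i_g = AiF * s["iF"] + (1.0 - AiF) * s["iS"]
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    gate("ap", assp, ta)
    dd = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                           + np.exp(-(v - 12.23) / 0.2154))
    dr = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    gate("iFp", iss, dd * dr * tiF)
    gate("iSp", iss, dd * dr * tiS)
    ip = AiF * s["iFp"] + (1.0 - AiF) * s["iSp"]
    Gto = 0.02 * (4.0 if (epi or mid) else 1.0)
    Ito = Gto * (v - EK) * ((1.0 - phi) * s["a"] * i_g + phi * s["ap"] * ip)

    # ICaL family
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    gate("d", dss, td)
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    gate("ff", fss, tff)
    gate("fs", fss, tfs)
    f = 0.6 * s["ff"] + 0.4 * s["fs"]
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    gate("fcaf", fss, tfcaf)
    gate("fcas", fss, tfcas)
    fca = Afcaf * s["fcaf"] + (1.0 - Afcaf) * s["fcas"]
    gate("jca", fss, 75.0)
    gate("ffp", fss, 2.5 * tff)
    fp_ = 0.6 * s["ffp"] + 0.4 * s["fs"]
    gate("fcafp", fss, 2.5 * tfcaf)
    fcap = Afcaf * s["fcafp"] + (1.0 - Afcaf) * s["fcas"]
    km2n = s["jca"] * 1.0
    anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / s["cass"]) ** 4)
    d["nca"] = anca * 1000.0 - s["nca"] * km2n
    PhiCaL = 4.0 * vffrt * (s["cass"] * np.exp(2 * vfrt) - 0.341 * cao) \
        / (np.exp(2 * vfrt) - 1.0)
    PhiCaNa = vffrt * (0.75 * s["nass"] * np.exp(vfrt) - 0.75 * nao) \
        / (np.exp(vfrt) - 1.0)
    PhiCaK = vffrt * (0.75 * s["kss"] * np.exp(vfrt) - 0.75 * ko) \
        / (np.exp(vfrt) - 1.0)
    PCa = 0.0001 * (1.2 if epi else 2.5 if mid else 1.0)
    nca = s["nca"]
    gfac = (f * (1.0 - nca) + s["jca"] * fca * nca)
    gfacp = (fp_ * (1.0 - nca) + s["jca"] * fcap * nca)
    ICaL = (1 - phi) * PCa * PhiCaL * s["d"] * gfac \
        + phi * 1.1 * PCa * PhiCaL * s["d"] * gfacp
    ICaNa = (1 - phi) * 0.00125 * PCa * PhiCaNa * s["d"] * gfac \
        + phi * 0.00125 * 1.1 * PCa * PhiCaNa * s["d"] * gfacp
    ICaK = (1 - phi) * 3.574e-4 * PCa * PhiCaK * s["d"] * gfac \
        + phi * 3.574e-4 * 1.1 * PCa * PhiCaK * s["d"] * gfacp

    # IKr
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    gate("xrf", xrss, txrf)
    gate("xrs", xrss, txrs)
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    xr = Axrf * s["xrf"] + (1.0 - Axrf) * s["xrs"]
    rkr = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0))
                 * (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * (1.3 if epi else 0.8 if mid else 1.0)
    IKr = GKr * np.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # IKs
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    gate("xs1", xs1ss, txs1)
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    gate("xs2", xs1ss, txs2)
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / s["cai"]) ** 1.4)
    GKs = 0.0034 * (1.4 if epi else 1.0)
    IKs = GKs * KsCa * s["xs1"] * s["xs2"] * (v - EKs)

    # IK1
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * ko + 144.59)
                                / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36)
                    + np.exp((v + 236.8) / 69.33))
    gate("xk1", xk1ss, txk1)
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908 * (1.2 if epi else 1.3 if mid else 1.0)
    IK1 = GK1 * np.sqrt(ko) * rk1 * s["xk1"] * (v - EK)

    # INaCa (shared machinery)
    def ncx(na_c, ca_c):
        kna1, kna2, kna3 = 15.0, 5.0, 88.12
        hca = np.exp(0.1670 * vfrt)
        hna = np.exp(0.5224 * vfrt)
        h1 = 1.0 + na_c / kna3 * (1.0 + hna)
        h2 = na_c * hna / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + na_c / kna1 * (1.0 + na_c / kna2)
        h5 = na_c * na_c / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
        h8 = nao / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = 12.5 + 1.0 + nao / kna1 * (1.0 + nao / kna2)
        h11 = nao * nao / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * cao * 1.5e6
        k2 = 5.0e3
        k3p = h9 * 6.0e4
        k3pp = h8 * 5.0e3
        k3 = k3p + k3pp
        k4p = h3 * 6.0e4 / hca
        k4pp = h2 * 5.0e3
        k4 = k4p + k4pp
        k5 = 5.0e3
        k6 = h6 * ca_c * 1.5e6
        k7 = h5 * h2 * 6.0e4
        k8 = h8 * h11 * 6.0e4
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        tot = x1 + x2 + x3 + x4
        E1, E2, E3, E4 = x1 / tot, x2 / tot, x3 / tot, x4 / tot
        allo = 1.0 / (1.0 + (150.0e-6 / ca_c) ** 2)
        JNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JCa = E2 * k2 - E1 * k1
        return allo * (JNa + 2.0 * JCa)

    Gncx = 0.0008 * (1.1 if epi else 1.4 if mid else 1.0)
    INaCa_i = 0.8 * Gncx * ncx(s["nai"], s["cai"])
    INaCa_ss = 0.2 * Gncx * ncx(s["nass"], s["cass"])

    # INaK
    Knai = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)
    P = 4.2 / (1.0 + 1.0e-7 / 1.698e-7 + s["nai"] / 224.0
               + s["ki"] / 292.0)
    den1 = (1.0 + s["nai"] / Knai) ** 3 + (1.0 + s["ki"] / 0.5) ** 2 - 1.0
    den2 = (1.0 + nao / Knao) ** 3 + (1.0 + ko / 0.3582) ** 2 - 1.0
    a1 = 949.5 * (s["nai"] / Knai) ** 3 / den1
    b1 = 182.4 * 0.05
    a2 = 687.2
    b2 = 39.4 * (nao / Knao) ** 3 / den2
    a3 = 1899.0 * (ko / 0.3582) ** 2 / den2
    b3 = 79300.0 * P * 1.0e-7 / (1.0 + 9.8 / 1.698e-7)
    a4 = (639.0 * 9.8 / 1.698e-7) / (1.0 + 9.8 / 1.698e-7)
    b4 = 40.0 * (s["ki"] / 0.5) ** 2 / den1
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    tot = x1 + x2 + x3 + x4
    E1, E2, E3, E4 = x1 / tot, x2 / tot, x3 / tot, x4 / tot
    Pnak = 30.0 * (0.9 if epi else 0.7 if mid else 1.0)
    INaK = Pnak * (3.0 * (E1 * a3 - E2 * b3) + 2.0 * (E4 * b1 - E3 * a1))

    # background / sarcolemmal pumps
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    IKb = 0.003 * (0.6 if epi else 1.0) * xkb * (v - EK)
    INab = 3.75e-10 * vffrt * (s["nai"] * np.exp(vfrt) - nao) \
        / (np.exp(vfrt) - 1.0)
    ICab = 2.5e-8 * 4.0 * vffrt * (s["cai"] * np.exp(2 * vfrt) - 0.341 * cao) \
        / (np.exp(2 * vfrt) - 1.0)
    IpCa = 0.0005 * s["cai"] / (0.0005 + s["cai"])

    # fluxes
    JdiffNa = (s["nass"] - s["nai"]) / 2.0
    JdiffK = (s["kss"] - s["ki"]) / 2.0
    Jdiff = (s["cass"] - s["cai"]) / 0.2
    bt = 4.75
    Jrel_inf = 0.5 * bt * (-ICaL) / (1.0 + (1.5 / s["cajsr"]) ** 8)
    if mid:
        Jrel_inf *= 1.7
    tau_rel = max(bt / (1.0 + 0.0123 / s["cajsr"]), 0.001)
    d["Jrelnp"] = (Jrel_inf - s["Jrelnp"]) / tau_rel
    btp = 1.25 * bt
    Jrel_infp = 0.5 * btp * (-ICaL) / (1.0 + (1.5 / s["cajsr"]) ** 8)
    if mid:
        Jrel_infp *= 1.7
    tau_relp = max(btp / (1.0 + 0.0123 / s["cajsr"]), 0.001)
    d["Jrelp"] = (Jrel_infp - s["Jrelp"]) / tau_relp
    Jrel = (1.0 - phi) * s["Jrelnp"] + phi * s["Jrelp"]
    Jupnp = 0.004375 * s["cai"] / (s["cai"] + 0.00092)
    Jupp = 2.75 * 0.004375 * s["cai"] / (s["cai"] + 0.00092 - 0.00017)
    if epi:
        Jupnp *= 1.3
        Jupp *= 1.3
    Jleak = 0.0039375 * s["cansr"] / 15.0
    Jup = (1.0 - phi) * Jupnp + phi * Jupp - Jleak
    Jtr = (s["cansr"] - s["cajsr"]) / 100.0

    cmdnmax = 0.05 * (1.3 if epi else 1.0)
    Bcai = 1.0 / (1.0 + cmdnmax * 0.00238 / (0.00238 + s["cai"]) ** 2
                  + 0.07 * 0.0005 / (0.0005 + s["cai"]) ** 2)
    Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + s["cass"]) ** 2
                   + 1.124 * 0.0087 / (0.0087 + s["cass"]) ** 2)
    Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + s["cajsr"]) ** 2)

    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab - istim)
    d["v"] = -Itot
    d["nai"] = (-(INa + INaL + 3 * INaCa_i + 3 * INaK + INab) * Acap
                / (F * vmyo) + JdiffNa * vss / vmyo)
    d["nass"] = -(ICaNa + 3 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    d["ki"] = (-(Ito + IKr + IKs + IK1 + IKb - istim - 2 * INaK) * Acap
               / (F * vmyo) + JdiffK * vss / vmyo)
    d["kss"] = -ICaK * Acap / (F * vss) - JdiffK
    d["cai"] = Bcai * (-(IpCa + ICab - 2 * INaCa_i) * Acap / (2 * F * vmyo)
                       - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    d["cass"] = Bcass * (-(ICaL - 2 * INaCa_ss) * Acap / (2 * F * vss)
                         + Jrel * vjsr / vss - Jdiff)
    d["cansr"] = Jup - Jtr * vjsr / vnsr
    d["cajsr"] = Bcajsr * (Jtr - Jrel)
    d["CaMKt"] = dCaMKt
    return np.array([d[name] for name in NAMES])
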