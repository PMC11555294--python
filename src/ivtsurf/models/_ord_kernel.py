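"""Numerical kernel of the O'Hara-Rudy (ORd, 2011) human ventricular model.

The right-hand side is transcribed from the model's published equation
supplement: 41 state variables (membrane potential, 8 ion concentrations,
Hodgkin-Huxley gates with CaMK-phosphorylated duplicates, SR release fluxes
and the CaMK trap), 16 membrane currents in A/F, time in ms, potentials in
mV, concentrations in mM.

The kernel is a single scalar-arithmetic function compiled with numba when
available (pure Python otherwise), shared by the free-running and the
voltage-clamped right-hand sides: under clamp dV/dt is forced to zero while
all gating and concentration equations keep evolving.

Cell-variant (endo/epi/M) and conductance-scale factors are folded into the
``cond`` parameter vector by :mod:`ivtsurf.models.ord` so the kernel itself
stays branch-free apart from the epi I_to kinetics flag.
"""

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# extracellular milieu and physical constants
NAO = 140.0
CAO = 1.8
KO = 5.4
RGAS = 8314.0
TEMP = 310.0
FARADAY = 96485.0

# cell geometry (cm); factor 3.14 as in the published code
L_CELL = 0.01
RAD = 0.0011
VCELL = 1000.0 * 3.14 * RAD * RAD * L_CELL
AGEO = 2.0 * 3.14 * RAD * RAD + 2.0 * 3.14 * RAD * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

N_STATES = 41
N_CURRENTS = 16

STATE_NAMES = (
    "v",
    "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)

CURRENT_NAMES = (
    "I_Na", "I_NaL", "I_to", "I_CaL", "I_CaNa", "I_CaK",
    "I_Kr", "I_Ks", "I_K1", "I_NaCa_i", "I_NaCa_ss", "I_NaK",
    "I_Nab", "I_Kb", "I_pCa", "I_Cab",
)

# indices into the cond vector assembled by ORdModel
IC_GNA, IC_GNAL, IC_GTO, IC_PCA, IC_GKR, IC_GKS, IC_GK1 = 0, 1, 2, 3, 4, 5, 6
IC_GNCX, IC_PNAK, IC_GKB, IC_PNAB, IC_PCAB, IC_GPCA = 7, 8, 9, 10, 11, 12
IC_JRELSC, IC_JUPSC, IC_CMDN, IC_EPIFLAG = 13, 14, 15, 16
N_COND = 17

# baseline (endocardial) maximal conductances / permeabilities
BASE_COND = np.zeros(N_COND)
BASE_COND[IC_GNA] = 75.0
BASE_COND[IC_GNAL] = 0.0075
BASE_COND[IC_GTO] = 0.02
BASE_COND[IC_PCA] = 0.0001
BASE_COND[IC_GKR] = 0.046
BASE_COND[IC_GKS] = 0.0034
BASE_COND[IC_GK1] = 0.1908
BASE_COND[IC_GNCX] = 0.0008
BASE_COND[IC_PNAK] = 30.0
BASE_COND[IC_GKB] = 0.003
BASE_COND[IC_PNAB] = 3.75e-10
BASE_COND[IC_PCAB] = 2.5e-8
BASE_COND[IC_GPCA] = 0.0005
BASE_COND[IC_JRELSC] = 1.0
BASE_COND[IC_JUPSC] = 1.0
BASE_COND[IC_CMDN] = 0.05
BASE_COND[IC_EPIFLAG] = 0.0

# published variant factors relative to endo
VARIANT_FACTORS = {
    "endo": {},
    "epi": {
        IC_GNAL: 0.6, IC_GTO: 4.0, IC_PCA: 1.2, IC_GKR: 1.3, IC_GKS: 1.4,
        IC_GK1: 1.2, IC_GNCX: 1.1, IC_PNAK: 0.9, IC_GKB: 0.6,
        IC_JUPSC: 1.3, IC_CMDN: 1.3, IC_EPIFLAG: None,
    },
    "M": {
        IC_GTO: 4.0, IC_PCA: 2.5, IC_GKR: 0.8, IC_GK1: 1.3,
        IC_GNCX: 1.4, IC_PNAK: 0.7, IC_JRELSC: 1.7,
    },
}

# initial conditions of the published code (conditioning pacing refines them)
Y0 = np.zeros(N_STATES)
Y0[0] = -87.0
Y0[1] = 7.0     # nai
Y0[2] = 7.0     # nass
Y0[3] = 145.0   # ki
Y0[4] = 145.0   # kss
Y0[5] = 1.0e-4  # cai
Y0[6] = 1.0e-4  # cass
Y0[7] = 1.2     # cansr
Y0[8] = 1.2     # cajsr
for _i, _n in enumerate(STATE_NAMES):
    if _n in ("hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS", "iFp",
              "iSp", "ff", "fs", "fcaf", "fcas", "jca", "xk1"):
        Y0[_i] = 1.0


@njit(cache=True)
def ord_rhs_currents(t, y, istim, cond, clamped):
    """Return (dy, currents) of the ORd model at state ``y``.

    ``istim`` is the injected current in A/F (cathodal negative); with
    ``clamped`` nonzero, dV/dt is forced to zero (membrane under ideal
    voltage clamp) and the stimulus is ignored.
    """
    dy = np.zeros(N_STATES)
    cur = np.zeros(N_CURRENTS)

    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    j = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    epi = cond[IC_EPIFLAG] > 0.5

    # CaMK (active fraction drives the phosphorylated-channel pathways)
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    # reversal potentials
    ENa = (RGAS * TEMP / FARADAY) * math.log(NAO / nai)
    EK = (RGAS * TEMP / FARADAY) * math.log(KO / ki)
    PKNa = 0.01833
    EKs = (RGAS * TEMP / FARADAY) * math.log((KO + PKNa * NAO) / (ki + PKNa * nai))

    vffrt = v * FARADAY * FARADAY / (RGAS * TEMP)
    vfrt = v * FARADAY / (RGAS * TEMP)

    # --- I_Na (fast) ---
    mss = 1.0 / (1.0 + math.exp((-(v + 39.57)) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    dy[9] = (mss - m) / tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285) + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05) + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    dy[10] = (hss - hf) / thf
    dy[11] = (hss - hs) / ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281) + 0.3052 * math.exp((v + 0.9941) / 38.45))
    dy[12] = (jss - j) / tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    dy[13] = (hssp - hsp) / thsp
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    dy[14] = (jss - jp) / tjp
    fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
    INa = cond[IC_GNA] * (v - ENa) * m ** 3 * ((1.0 - fINap) * h * j + fINap * hp * jp)

    # --- I_NaL ---
    mLss = 1.0 / (1.0 + math.exp((-(v + 42.85)) / 5.264))
    tmL = tm
    dy[15] = (mLss - mL) / tmL
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    dy[16] = (hLss - hL) / thL
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    dy[17] = (hLssp - hLp) / thLp
    fINaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    INaL = cond[IC_GNAL] * (v - ENa) * mL * ((1.0 - fINaLp) * hL + fINaLp * hLp)

    # --- I_to ---
    ass = 1.0 / (1.0 + math.exp((-(v - 14.34)) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    dy[18] = (ass - a) / ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if epi:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp((-(v + 100.0)) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp((-(v + 96.52)) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF = tiF * delta_epi
    tiS = tiS * delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    dy[19] = (iss - iF) / tiF
    dy[20] = (iss - iS) / tiS
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp((-(v - 24.34)) / 14.82))
    dy[21] = (assp - ap) / ta
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    dy[22] = (iss - iFp) / tiFp
    dy[23] = (iss - iSp) / tiSp
    ip = AiF * iFp + AiS * iSp
    fItop = 1.0 / (1.0 + KmCaMK / CaMKa)
    Ito = cond[IC_GTO] * (v - EK) * ((1.0 - fItop) * a * i_gate + fItop * ap * ip)

    # --- I_CaL / I_CaNa / I_CaK ---
    dss = 1.0 / (1.0 + math.exp((-(v + 3.940)) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    dy[24] = (dss - d) / td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    dy[25] = (fss - ff) / tff
    dy[26] = (fss - fs) / tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    dy[27] = (fcass - fcaf) / tfcaf
    dy[28] = (fcass - fcas) / tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    dy[29] = (fcass - jca) / tjca
    ktaup = 2.5
    tffp = ktaup * tff
    dy[31] = (fss - ffp) / tffp
    fp = Aff * ffp + Afs * fs
    tfcafp = ktaup * tfcaf
    dy[32] = (fcass - fcafp) / tfcafp
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4.0)
    dy[30] = anca * k2n - nca * km2n
    # driving-force limits at v = 0 resolve the 0/0 of the GHK flux
    if abs(vfrt) < 1e-7:
        PhiCaL = 2.0 * FARADAY * (cass - 0.341 * CAO)
        PhiCaNa = FARADAY * (0.75 * nass - 0.75 * NAO)
        PhiCaK = FARADAY * (0.75 * kss - 0.75 * KO)
    else:
        PhiCaL = 4.0 * vffrt * (cass * math.exp(2.0 * vfrt) - 0.341 * CAO) / (math.exp(2.0 * vfrt) - 1.0)
        PhiCaNa = 1.0 * vffrt * (0.75 * nass * math.exp(1.0 * vfrt) - 0.75 * NAO) / (math.exp(1.0 * vfrt) - 1.0)
        PhiCaK = 1.0 * vffrt * (0.75 * kss * math.exp(1.0 * vfrt) - 0.75 * KO) / (math.exp(1.0 * vfrt) - 1.0)
    PCa = cond[IC_PCA]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fICaLp) * PCa * PhiCaL * gate_np + fICaLp * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fICaLp) * PCaNa * PhiCaNa * gate_np + fICaLp * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fICaLp) * PCaK * PhiCaK * gate_np + fICaLp * PCaKp * PhiCaK * gate_p

    # --- I_Kr ---
    xrss = 1.0 / (1.0 + math.exp((-(v + 8.337)) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp((-(v - 47.78)) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp((-(v - 29.74)) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    dy[33] = (xrss - xrf) / txrf
    dy[34] = (xrss - xrs) / txrs
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + math.exp((v + 55.0) / 75.0)) * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0))
    IKr = cond[IC_GKR] * math.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    # --- I_Ks ---
    xs1ss = 1.0 / (1.0 + math.exp((-(v + 11.60)) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp((-(v + 210.0)) / 230.0))
    dy[35] = (xs1ss - xs1) / txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp((-(v + 66.54)) / 31.0))
    dy[36] = (xs2ss - xs2) / txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = cond[IC_GKS] * KsCa * xs1 * xs2 * (v - EKs)

    # --- I_K1 ---
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * KO + 144.59) / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (math.exp((-(v + 127.2)) / 20.36) + math.exp((v + 236.8) / 69.33))
    dy[37] = (xk1ss - xk1) / txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * KO) / 9.493))
    IK1 = cond[IC_GK1] * math.sqrt(KO) * rk1 * xk1 * (v - EK)

    # --- I_NaCa (sarcolemmal Na/Ca exchanger, myoplasmic & subspace) ---
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
    hca = math.exp((qca * v * FARADAY) / (RGAS * TEMP))
    hna = math.exp((qna * v * FARADAY) / (RGAS * TEMP))
    zca = 2.0
    zna = 1.0

    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
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
    xtot = x1 + x2 + x3 + x4
    E1 = x1 / xtot
    E2 = x2 / xtot
    E3 = x3 / xtot
    E4 = x4 / xtot
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * cond[IC_GNCX] * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * CAO * kcaon
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    xtot = x1 + x2 + x3 + x4
    E1 = x1 / xtot
    E2 = x2 / xtot
    E3 = x3 / xtot
    E4 = x4 / xtot
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * cond[IC_GNCX] * allo_ss * (zna * JncxNa + zca * JncxCa)

    # --- I_NaK (Na/K ATPase, Smith-Crampin scheme) ---
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp((delta * v * FARADAY) / (3.0 * RGAS * TEMP))
    Knao = Knao0 * math.exp(((1.0 - delta) * v * FARADAY) / (3.0 * RGAS * TEMP))
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
    a1 = (k1p * (nai / Knai) ** 3.0) / ((1.0 + nai / Knai) ** 3.0 + (1.0 + ki / Kki) ** 2.0 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (NAO / Knao) ** 3.0) / ((1.0 + NAO / Knao) ** 3.0 + (1.0 + KO / Kko) ** 2.0 - 1.0)
    a3 = (k3p * (KO / Kko) ** 2.0) / ((1.0 + NAO / Knao) ** 3.0 + (1.0 + KO / Kko) ** 2.0 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2.0) / ((1.0 + nai / Knai) ** 3.0 + (1.0 + ki / Kki) ** 2.0 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    xtot = x1 + x2 + x3 + x4
    E1 = x1 / xtot
    E2 = x2 / xtot
    E3 = x3 / xtot
    E4 = x4 / xtot
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = cond[IC_PNAK] * (zna * JnakNa + zk * JnakK)

    # --- background and pump currents ---
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = cond[IC_GKB] * xkb * (v - EK)
    if abs(vfrt) < 1e-7:
        INab = cond[IC_PNAB] * FARADAY * (nai - NAO)
        ICab = cond[IC_PCAB] * 2.0 * FARADAY * (cai - 0.341 * CAO)
    else:
        INab = cond[IC_PNAB] * vffrt * (nai * math.exp(vfrt) - NAO) / (math.exp(vfrt) - 1.0)
        ICab = cond[IC_PCAB] * 4.0 * vffrt * (cai * math.exp(2.0 * vfrt) - 0.341 * CAO) / (math.exp(2.0 * vfrt) - 1.0)
    IpCa = cond[IC_GPCA] * cai / (0.0005 + cai)

    # --- intracellular fluxes ---
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = cond[IC_JRELSC] * a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dy[38] = (Jrel_inf - Jrelnp) / tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = cond[IC_JRELSC] * a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dy[39] = (Jrel_infp - Jrelp) / tau_relp
    fJrelp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jrel = (1.0 - fJrelp) * Jrelnp + fJrelp * Jrelp

    Jupnp = cond[IC_JUPSC] * 0.004375 * cai / (cai + 0.00092)
    Jupp = cond[IC_JUPSC] * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    fJupp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- concentration balances ---
    cmdnmax = cond[IC_CMDN]
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    ist = 0.0 if clamped else istim
    dy[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * ACAP / (FARADAY * VMYO) + JdiffNa * VSS / VMYO
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * ACAP / (FARADAY * VSS) - JdiffNa
    dy[3] = -(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * ACAP / (FARADAY * VMYO) + JdiffK * VSS / VMYO
    dy[4] = -ICaK * ACAP / (FARADAY * VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2.0 + trpnmax * kmtrpn / (kmtrpn + cai) ** 2.0)
    dy[5] = Bcai * (
        -(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * FARADAY * VMYO)
        - Jup * VNSR / VMYO
        + Jdiff * VSS / VMYO
    )
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2.0 + BSLmax * KmBSL / (KmBSL + cass) ** 2.0)
    dy[6] = Bcass * (
        -(ICaL - 2.0 * INaCa_ss) * ACAP / (2.0 * FARADAY * VSS) + Jrel * VJSR / VSS - Jdiff
    )
    dy[7] = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2.0)
    dy[8] = Bcajsr * (Jtr - Jrel)

    cur[0] = INa
    cur[1] = INaL
    cur[2] = Ito
    cur[3] = ICaL
    cur[4] = ICaNa
    cur[5] = ICaK
    cur[6] = IKr
    cur[7] = IKs
    cur[8] = IK1
    cur[9] = INaCa_i
    cur[10] = INaCa_ss
    cur[11] = INaK
    cur[12] = INab
    cur[13] = IKb
    cur[14] = IpCa
    cur[15] = ICab

    if clamped:
        dy[0] = 0.0
    else:
        iion = 0.0
        for kk in range(N_CURRENTS):
            iion += cur[kk]
        dy[0] = -(iion + istim)

    return dy, cur
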