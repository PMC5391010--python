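"""Compiled numerical kernels for the coupled myocyte ODE system.

All model arithmetic lives here, operating on flat float64 arrays whose
layouts are fixed by :mod:`cardioec.registry` (states),
:mod:`cardioec.parameters` (constants) and :mod:`cardioec.disease`
(impact factors).  The Python-facing API in :mod:`cardioec.gpb` and
:mod:`cardioec.nhs` wraps these kernels with validation and naming.

Rate expressions of the form x/(1 - e^{-kx}) and the GHK flux factor
u/(e^u - 1) have removable singularities at reachable voltages; every
such expression goes through a series-guarded helper (|arg| < 1e-4).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(func):
            return func
        if args and callable(args[0]):
            return args[0]
        return wrap

from . import parameters as P
from . import registry as R

CURRENT_NAMES: list[str] = [
    "I_Na_junc", "I_Na_sl", "I_Na",
    "I_NaL_junc", "I_NaL_sl", "I_NaL",
    "I_nabk_junc", "I_nabk_sl", "I_nabk",
    "I_nak_junc", "I_nak_sl", "I_nak",
    "I_kr", "I_ks", "I_kp", "I_tos", "I_tof", "I_to", "I_ki",
    "I_ClCa", "I_Clbk",
    "I_Ca_junc", "I_Ca_sl", "I_Ca", "I_CaK",
    "I_CaNa_junc", "I_CaNa_sl", "I_CaNa",
    "I_ncx_junc", "I_ncx_sl", "I_ncx",
    "I_pca_junc", "I_pca_sl", "I_pca",
    "I_cabk_junc", "I_cabk_sl", "I_cabk",
    "J_SRCarel", "J_serca", "J_SRleak",
]
CURRENT_INDEX: dict[str, int] = {n: i for i, n in enumerate(CURRENT_NAMES)}
N_CURRENTS = len(CURRENT_NAMES)

for _i, _n in enumerate(CURRENT_NAMES):
    globals()["C_" + _n.upper()] = _i


@njit(cache=True)
def _xexprel(x):
    """x / (1 - exp(-x)) with the analytic limit 1 at x = 0."""
    if abs(x) < 1e-4:
        return 1.0 + 0.5 * x + x * x / 12.0
    return x / (1.0 - math.exp(-x))


@njit(cache=True)
def _relexp(x):
    """(1 - exp(-x)) / x with the analytic limit 1 at x = 0."""
    if abs(x) < 1e-4:
        return 1.0 - 0.5 * x + x * x / 6.0
    return (1.0 - math.exp(-x)) / x


@njit(cache=True)
def _u_over_expm1(u):
    """u / (exp(u) - 1) with the analytic limit 1 at u = 0."""
    if abs(u) < 1e-4:
        return 1.0 - 0.5 * u + u * u / 12.0
    return u / math.expm1(u)


@njit(cache=True)
def late_na_rates(Vm, tau_hL, f_hl):
    """Late-Na gate kinetics: (alpha_mL, beta_mL, hL_inf, tau_hL_eff)."""
    alpha_mL = 3.2 * _xexprel(0.1 * (Vm + 47.13))
    beta_mL = 0.08 * math.exp(-Vm / 11.0)
    hL_inf = 1.0 / (1.0 + math.exp((Vm + 91.0) / 6.1))
    return alpha_mL, beta_mL, hL_inf, f_hl * tau_hL


@njit(cache=True)
def compute_currents_arr(y, p, f):
    """Evaluate every ionic current/flux at the given state.

    Membrane currents in uA/uF; SR fluxes (J_*) in mM/ms.
    """
    cur = np.zeros(N_CURRENTS)

    Vm = y[R.S_VM]
    Naj = y[R.S_NAJ]
    Nasl = y[R.S_NASL]
    Nai = y[R.S_NAI]
    Ki = y[R.S_KI]
    Caj = y[R.S_CAJ]
    Casl = y[R.S_CASL]
    Ca_sr = y[R.S_CA_SR]

    FoRT = p[P.P_FRDY] / (p[P.P_R] * p[P.P_TEMP])
    Qpow = (p[P.P_TEMP] - 310.0) / 10.0

    Fjunc = p[P.P_FJUNC]
    Fsl = p[P.P_FSL]
    Nao = p[P.P_NAO]
    Ko = p[P.P_KO]
    Cao = p[P.P_CAO]

    ena_junc = (1.0 / FoRT) * math.log(Nao / Naj)
    ena_sl = (1.0 / FoRT) * math.log(Nao / Nasl)
    ek = (1.0 / FoRT) * math.log(Ko / Ki)
    eca_junc = (0.5 / FoRT) * math.log(Cao / Caj)
    eca_sl = (0.5 / FoRT) * math.log(Cao / Casl)
    ecl = (1.0 / FoRT) * math.log(p[P.P_CLI] / p[P.P_CLO])

    # fast Na
    GNa = p[P.P_GNA]
    m3hj = y[R.S_M] ** 3 * y[R.S_H] * y[R.S_J]
    cur[C_I_NA_JUNC] = Fjunc * GNa * m3hj * (Vm - ena_junc)
    cur[C_I_NA_SL] = Fsl * GNa * m3hj * (Vm - ena_sl)
    cur[C_I_NA] = cur[C_I_NA_JUNC] + cur[C_I_NA_SL]

    # late Na (model extension; scaled by impact factor f_NaL)
    gNaL = p[P.P_GNAL] * f[1]
    mL3hL = y[R.S_ML] ** 3 * y[R.S_HL]
    cur[C_I_NAL_JUNC] = Fjunc * gNaL * mL3hL * (Vm - ena_junc)
    cur[C_I_NAL_SL] = Fsl * gNaL * mL3hL * (Vm - ena_sl)
    cur[C_I_NAL] = cur[C_I_NAL_JUNC] + cur[C_I_NAL_SL]

    # background Na (f_Nabk)
    GNaB = p[P.P_GNAB] * f[4]
    cur[C_I_NABK_JUNC] = Fjunc * GNaB * (Vm - ena_junc)
    cur[C_I_NABK_SL] = Fsl * GNaB * (Vm - ena_sl)
    cur[C_I_NABK] = cur[C_I_NABK_JUNC] + cur[C_I_NABK_SL]

    # Na/K pump (f_NaK)
    sigma = (math.exp(Nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * Vm * FoRT)
                  + 0.0365 * sigma * math.exp(-Vm * FoRT))
    IbarNaK = p[P.P_IBARNAK] * f[3]
    KmNaip = p[P.P_KMNAIP]
    KmKo = p[P.P_KMKO]
    cur[C_I_NAK_JUNC] = (Fjunc * IbarNaK * fnak * Ko
                         / (1.0 + (KmNaip / Naj) ** 4) / (Ko + KmKo))
    cur[C_I_NAK_SL] = (Fsl * IbarNaK * fnak * Ko
                       / (1.0 + (KmNaip / Nasl) ** 4) / (Ko + KmKo))
    cur[C_I_NAK] = cur[C_I_NAK_JUNC] + cur[C_I_NAK_SL]

    # rapid delayed rectifier
    gkr = p[P.P_GKR] * math.sqrt(Ko / 5.4)
    rkr = 1.0 / (1.0 + math.exp((Vm + 74.0) / 24.0))
    cur[C_I_KR] = gkr * y[R.S_XKR] * rkr * (Vm - ek)

    # slow delayed rectifier
    eks = (1.0 / FoRT) * math.log((Ko + p[P.P_PNAK] * Nao)
                                  / (Ki + p[P.P_PNAK] * Nai))
    cur[C_I_KS] = p[P.P_GKS] * y[R.S_XKS] ** 2 * (Vm - eks)

    # plateau K
    kp_kp = 1.0 / (1.0 + math.exp(7.488 - Vm / 5.98))
    cur[C_I_KP] = p[P.P_GKP] * kp_kp * (Vm - ek)

    # transient outward (f_to)
    cur[C_I_TOS] = (p[P.P_GTOSLOW] * f[7] * y[R.S_XTOS] * y[R.S_YTOS]
                    * (Vm - ek))
    cur[C_I_TOF] = (p[P.P_GTOFAST] * f[7] * y[R.S_XTOF] * y[R.S_YTOF]
                    * (Vm - ek))
    cur[C_I_TO] = cur[C_I_TOS] + cur[C_I_TOF]

    # inward rectifier (f_Ki)
    aki = 1.02 / (1.0 + math.exp(0.2385 * (Vm - ek - 59.215)))
    bki = ((0.49124 * math.exp(0.08032 * (Vm + 5.476 - ek))
            + math.exp(0.06175 * (Vm - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (Vm - ek + 4.753))))
    kiss = aki / (aki + bki)
    cur[C_I_KI] = (p[P.P_GKI] * f[2] * math.sqrt(Ko / 5.4) * kiss * (Vm - ek))

    # Ca-activated and background Cl
    GClCa = p[P.P_GCLCA]
    KdClCa = p[P.P_KDCLCA]
    cur[C_I_CLCA] = (Fjunc * GClCa / (1.0 + KdClCa / Caj) * (Vm - ecl)
                     + Fsl * GClCa / (1.0 + KdClCa / Casl) * (Vm - ecl))
    cur[C_I_CLBK] = p[P.P_GCLB] * (Vm - ecl)

    # L-type Ca (GHK fluxes); u = z*Vm*F/RT
    Frdy = p[P.P_FRDY]
    u2 = 2.0 * Vm * FoRT
    u1 = Vm * FoRT
    A2 = _u_over_expm1(u2)
    A1 = _u_over_expm1(u1)
    # P*z*F*( gi*Ci*(u+A) - go*Co*A ) with (u+A) = u*e^u/(e^u-1)
    ibarca_j = p[P.P_PCA] * 2.0 * Frdy * (0.341 * Caj * (u2 + A2)
                                          - 0.341 * Cao * A2)
    ibarca_sl = p[P.P_PCA] * 2.0 * Frdy * (0.341 * Casl * (u2 + A2)
                                           - 0.341 * Cao * A2)
    ibark = p[P.P_PK] * Frdy * (0.75 * Ki * (u1 + A1) - 0.75 * Ko * A1)
    ibarna_j = p[P.P_PNA] * Frdy * (0.75 * Naj * (u1 + A1) - 0.75 * Nao * A1)
    ibarna_sl = p[P.P_PNA] * Frdy * (0.75 * Nasl * (u1 + A1) - 0.75 * Nao * A1)

    df_gate = y[R.S_D] * y[R.S_F]
    q_cal = p[P.P_Q10CAL] ** Qpow * p[P.P_ICAL_SCALE]
    Fj_CaL = p[P.P_FJUNC_CAL]
    Fsl_CaL = p[P.P_FSL_CAL]
    cur[C_I_CA_JUNC] = (Fj_CaL * ibarca_j * df_gate * (1.0 - y[R.S_FCABJ])
                        * q_cal)
    cur[C_I_CA_SL] = (Fsl_CaL * ibarca_sl * df_gate * (1.0 - y[R.S_FCABSL])
                      * q_cal)
    cur[C_I_CA] = cur[C_I_CA_JUNC] + cur[C_I_CA_SL]
    cur[C_I_CAK] = (ibark * df_gate
                    * (Fj_CaL * (1.0 - y[R.S_FCABJ])
                       + Fsl_CaL * (1.0 - y[R.S_FCABSL])) * q_cal)
    cur[C_I_CANA_JUNC] = (Fj_CaL * ibarna_j * df_gate * (1.0 - y[R.S_FCABJ])
                          * q_cal)
    cur[C_I_CANA_SL] = (Fsl_CaL * ibarna_sl * df_gate * (1.0 - y[R.S_FCABSL])
                        * q_cal)
    cur[C_I_CANA] = cur[C_I_CANA_JUNC] + cur[C_I_CANA_SL]

    # Na/Ca exchanger (f_ncx)
    Kdact = p[P.P_KDACT]
    KmCai = p[P.P_KMCAI]
    KmCao = p[P.P_KMCAO]
    KmNai = p[P.P_KMNAI]
    KmNao = p[P.P_KMNAO]
    nu = p[P.P_NU]
    ksat = p[P.P_KSAT]
    IbarNCX = p[P.P_IBARNCX] * f[6] * p[P.P_Q10NCX] ** Qpow
    Ka_junc = 1.0 / (1.0 + (Kdact / Caj) ** 2)
    Ka_sl = 1.0 / (1.0 + (Kdact / Casl) ** 2)
    expnu = math.exp(nu * Vm * FoRT)
    expnum1 = math.exp((nu - 1.0) * Vm * FoRT)
    s1_j = expnu * Naj ** 3 * Cao
    s2_j = expnum1 * Nao ** 3 * Caj
    s3_j = (KmCai * Nao ** 3 * (1.0 + (Naj / KmNai) ** 3)
            + KmNao ** 3 * Caj * (1.0 + Caj / KmCai)
            + KmCao * Naj ** 3 + Naj ** 3 * Cao + Nao ** 3 * Caj)
    s1_sl = expnu * Nasl ** 3 * Cao
    s2_sl = expnum1 * Nao ** 3 * Casl
    s3_sl = (KmCai * Nao ** 3 * (1.0 + (Nasl / KmNai) ** 3)
             + KmNao ** 3 * Casl * (1.0 + Casl / KmCai)
             + KmCao * Nasl ** 3 + Nasl ** 3 * Cao + Nao ** 3 * Casl)
    denom = 1.0 + ksat * expnum1
    cur[C_I_NCX_JUNC] = Fjunc * IbarNCX * Ka_junc * (s1_j - s2_j) / s3_j / denom
    cur[C_I_NCX_SL] = Fsl * IbarNCX * Ka_sl * (s1_sl - s2_sl) / s3_sl / denom
    cur[C_I_NCX] = cur[C_I_NCX_JUNC] + cur[C_I_NCX_SL]

    # sarcolemmal Ca pump
    IbarSLCaP = p[P.P_IBARSLCAP] * p[P.P_Q10SLCAP] ** Qpow
    KmPCa16 = p[P.P_KMPCA] ** 1.6
    cur[C_I_PCA_JUNC] = (Fjunc * IbarSLCaP * Caj ** 1.6
                         / (KmPCa16 + Caj ** 1.6))
    cur[C_I_PCA_SL] = (Fsl * IbarSLCaP * Casl ** 1.6
                       / (KmPCa16 + Casl ** 1.6))
    cur[C_I_PCA] = cur[C_I_PCA_JUNC] + cur[C_I_PCA_SL]

    # background Ca (f_Cabk)
    GCaB = p[P.P_GCAB] * f[5]
    cur[C_I_CABK_JUNC] = Fjunc * GCaB * (Vm - eca_junc)
    cur[C_I_CABK_SL] = Fsl * GCaB * (Vm - eca_sl)
    cur[C_I_CABK] = cur[C_I_CABK_JUNC] + cur[C_I_CABK_SL]

    # SR release (RyR), uptake (SERCA, f_SRca), leak (f_SRleak);
    # EC50 of luminal-Ca release sensitivity scaled by f_EC50SR
    cur[C_J_SRCAREL] = p[P.P_KS] * y[R.S_RYR_O] * (Ca_sr - Caj)
    q_srcap = p[P.P_Q10SRCAP] ** Qpow
    Cai = y[R.S_CAI]
    kmf_t = (Cai / p[P.P_KMF]) ** p[P.P_HILLSRCAP]
    kmr_t = (Ca_sr / p[P.P_KMR]) ** p[P.P_HILLSRCAP]
    cur[C_J_SERCA] = (q_srcap * p[P.P_VMAX_SRCAP] * f[9] * (kmf_t - kmr_t)
                      / (1.0 + kmf_t + kmr_t))
    cur[C_J_SRLEAK] = p[P.P_LEAK_RATE] * f[8] * (Ca_sr - Caj)

    return cur


@njit(cache=True)
def gpb_derivs(y, p, f, i_stim):
    """Time derivative of the electrophysiology block (states 0..hL).

    ``i_stim`` is the applied stimulus in uA/uF, positive depolarizing.
    NHS entries of the returned vector are left at zero.
    """
    dydt = np.zeros(y.shape[0])
    cur = compute_currents_arr(y, p, f)

    Vm = y[R.S_VM]

    # -- fast Na gates (piecewise Luo-Rudy style h/j kinetics)
    mss = 1.0 / (1.0 + math.exp(-(56.86 + Vm) / 9.03)) ** 2
    taum = (0.1292 * math.exp(-((Vm + 45.79) / 15.54) ** 2)
            + 0.06487 * math.exp(-((Vm - 4.823) / 51.12) ** 2))
    if Vm >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(Vm + 10.66) / 11.1)))
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * Vm)
              / (1.0 + math.exp(-0.1 * (Vm + 32.0))))
    else:
        ah = 0.057 * math.exp(-(Vm + 80.0) / 6.8)
        bh = (2.7 * math.exp(0.079 * Vm) + 3.1e5 * math.exp(0.3485 * Vm))
        aj = (((-2.5428e4 * math.exp(0.2444 * Vm)
                - 6.948e-6 * math.exp(-0.04391 * Vm)) * (Vm + 37.78))
              / (1.0 + math.exp(0.311 * (Vm + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * Vm)
              / (1.0 + math.exp(-0.1378 * (Vm + 40.14))))
    tauh = 1.0 / (ah + bh)
    hss = 1.0 / (1.0 + math.exp((Vm + 71.55) / 7.43)) ** 2
    tauj = 1.0 / (aj + bj)
    jss = hss
    dydt[R.S_M] = (mss - y[R.S_M]) / taum
    dydt[R.S_H] = (hss - y[R.S_H]) / tauh
    dydt[R.S_J] = (jss - y[R.S_J]) / tauj

    # -- late Na gates
    a_mL, b_mL, hL_inf, tau_hL_eff = late_na_rates(Vm, p[P.P_TAU_HL], f[0])
    dydt[R.S_ML] = a_mL * (1.0 - y[R.S_ML]) - b_mL * y[R.S_ML]
    dydt[R.S_HL] = (hL_inf - y[R.S_HL]) / tau_hL_eff

    # -- L-type Ca gates
    dss = 1.0 / (1.0 + math.exp(-(Vm + 5.0) / 6.0))
    # dss*(1-e^{-(Vm+5)/6})/(0.035*(Vm+5)), series-guarded at Vm = -5
    taud = dss * _relexp((Vm + 5.0) / 6.0) / 0.21
    fss = (1.0 / (1.0 + math.exp((Vm + 35.0) / 9.0))
           + 0.6 / (1.0 + math.exp((50.0 - Vm) / 20.0)))
    tauf = 1.0 / (0.0197 * math.exp(-(0.0337 * (Vm + 14.5)) ** 2) + 0.02)
    dydt[R.S_D] = (dss - y[R.S_D]) / taud
    dydt[R.S_F] = (fss - y[R.S_F]) / tauf
    dydt[R.S_FCABJ] = 1.7 * y[R.S_CAJ] * (1.0 - y[R.S_FCABJ]) \
        - 11.9e-3 * y[R.S_FCABJ]
    dydt[R.S_FCABSL] = 1.7 * y[R.S_CASL] * (1.0 - y[R.S_FCABSL]) \
        - 11.9e-3 * y[R.S_FCABSL]

    # -- transient outward gates
    xtoss = 1.0 / (1.0 + math.exp(-(Vm - 19.0) / 13.0))
    ytoss = 1.0 / (1.0 + math.exp((Vm + 19.5) / 5.0))
    tauxtos = 9.0 / (1.0 + math.exp((Vm + 3.0) / 15.0)) + 0.5
    tauytos = 800.0 / (1.0 + math.exp((Vm + 60.0) / 10.0)) + 30.0
    tauxtof = 8.5 * math.exp(-((Vm + 45.0) / 50.0) ** 2) + 0.5
    tauytof = 85.0 * math.exp(-((Vm + 40.0) ** 2) / 220.0) + 7.0
    dydt[R.S_XTOS] = (xtoss - y[R.S_XTOS]) / tauxtos
    dydt[R.S_YTOS] = (ytoss - y[R.S_YTOS]) / tauytos
    dydt[R.S_XTOF] = (xtoss - y[R.S_XTOF]) / tauxtof
    dydt[R.S_YTOF] = (ytoss - y[R.S_YTOF]) / tauytof

    # -- delayed rectifier gates
    xrss = 1.0 / (1.0 + math.exp(-(Vm + 10.0) / 5.0))
    tauxr = (550.0 / (1.0 + math.exp((-22.0 - Vm) / 9.0))
             * 6.0 / (1.0 + math.exp((Vm + 11.0) / 9.0))
             + 230.0 / (1.0 + math.exp((Vm + 40.0) / 20.0)))
    xsss = 1.0 / (1.0 + math.exp(-(Vm + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + math.exp(-(Vm + 2.436) / 14.12))
    dydt[R.S_XKR] = (xrss - y[R.S_XKR]) / tauxr
    dydt[R.S_XKS] = (xsss - y[R.S_XKS]) / tauxs

    # -- RyR states (luminal-Ca-sensitive release; f_EC50SR on ec50SR)
    Caj = y[R.S_CAJ]
    Ca_sr = y[R.S_CA_SR]
    MaxSR = p[P.P_MAXSR]
    MinSR = p[P.P_MINSR]
    ec50 = p[P.P_EC50SR] * f[10]
    kCaSR = MaxSR - (MaxSR - MinSR) / (1.0 + (ec50 / Ca_sr) ** 2.5)
    koSRCa = p[P.P_KOCA] / kCaSR
    kiSRCa = p[P.P_KICA] * kCaSR
    kom = p[P.P_KOM]
    kim = p[P.P_KIM]
    ryr_r = y[R.S_RYR_R]
    ryr_o = y[R.S_RYR_O]
    ryr_i = y[R.S_RYR_I]
    RI = 1.0 - ryr_r - ryr_o - ryr_i
    dydt[R.S_RYR_R] = ((kim * RI - kiSRCa * Caj * ryr_r)
                       - (koSRCa * Caj ** 2 * ryr_r - kom * ryr_o))
    dydt[R.S_RYR_O] = ((koSRCa * Caj ** 2 * ryr_r - kom * ryr_o)
                       - (kiSRCa * Caj * ryr_o - kim * ryr_i))
    dydt[R.S_RYR_I] = ((kiSRCa * Caj * ryr_o - kim * ryr_i)
                       - (kom * ryr_i - koSRCa * Caj ** 2 * RI))

    # -- Na buffering
    dydt[R.S_NABJ] = (p[P.P_KON_NA] * y[R.S_NAJ]
                      * (p[P.P_BMAX_NAJ] - y[R.S_NABJ])
                      - p[P.P_KOFF_NA] * y[R.S_NABJ])
    dydt[R.S_NABSL] = (p[P.P_KON_NA] * y[R.S_NASL]
                       * (p[P.P_BMAX_NASL] - y[R.S_NABSL])
                       - p[P.P_KOFF_NA] * y[R.S_NABSL])

    # -- cytosolic Ca buffers
    Cai = y[R.S_CAI]
    Mgi = p[P.P_MGI]
    dydt[R.S_TNCL] = (p[P.P_KON_TNCL] * Cai
                      * (p[P.P_BMAX_TNCLOW] - y[R.S_TNCL])
                      - p[P.P_KOFF_TNCL] * y[R.S_TNCL])
    free_tnch = p[P.P_BMAX_TNCHIGH] - y[R.S_TNCHC] - y[R.S_TNCHM]
    dydt[R.S_TNCHC] = (p[P.P_KON_TNCHCA] * Cai * free_tnch
                       - p[P.P_KOFF_TNCHCA] * y[R.S_TNCHC])
    dydt[R.S_TNCHM] = (p[P.P_KON_TNCHMG] * Mgi * free_tnch
                       - p[P.P_KOFF_TNCHMG] * y[R.S_TNCHM])
    dydt[R.S_CAM] = (p[P.P_KON_CAM] * Cai * (p[P.P_BMAX_CAM] - y[R.S_CAM])
                     - p[P.P_KOFF_CAM] * y[R.S_CAM])
    free_myo = p[P.P_BMAX_MYOSIN] - y[R.S_MYOC] - y[R.S_MYOM]
    dydt[R.S_MYOC] = (p[P.P_KON_MYOCA] * Cai * free_myo
                      - p[P.P_KOFF_MYOCA] * y[R.S_MYOC])
    dydt[R.S_MYOM] = (p[P.P_KON_MYOMG] * Mgi * free_myo
                      - p[P.P_KOFF_MYOMG] * y[R.S_MYOM])
    dydt[R.S_SRB] = (p[P.P_KON_SR] * Cai * (p[P.P_BMAX_SR] - y[R.S_SRB])
                     - p[P.P_KOFF_SR] * y[R.S_SRB])
    # net Ca consumed by cytosolic buffers (Mg-binding states do not move Ca)
    J_CaB_cytosol = (dydt[R.S_TNCL] + dydt[R.S_TNCHC] + dydt[R.S_CAM]
                     + dydt[R.S_MYOC] + dydt[R.S_SRB])

    # -- junctional and subsarcolemmal Ca buffers
    dydt[R.S_SLLJ] = (p[P.P_KON_SLL] * Caj * (p[P.P_BMAX_SLLOWJ] - y[R.S_SLLJ])
                      - p[P.P_KOFF_SLL] * y[R.S_SLLJ])
    dydt[R.S_SLLSL] = (p[P.P_KON_SLL] * y[R.S_CASL]
                       * (p[P.P_BMAX_SLLOWSL] - y[R.S_SLLSL])
                       - p[P.P_KOFF_SLL] * y[R.S_SLLSL])
    dydt[R.S_SLHJ] = (p[P.P_KON_SLH] * Caj * (p[P.P_BMAX_SLHIGHJ] - y[R.S_SLHJ])
                      - p[P.P_KOFF_SLH] * y[R.S_SLHJ])
    dydt[R.S_SLHSL] = (p[P.P_KON_SLH] * y[R.S_CASL]
                       * (p[P.P_BMAX_SLHIGHSL] - y[R.S_SLHSL])
                       - p[P.P_KOFF_SLH] * y[R.S_SLHSL])
    J_CaB_junction = dydt[R.S_SLLJ] + dydt[R.S_SLHJ]
    J_CaB_sl = dydt[R.S_SLLSL] + dydt[R.S_SLHSL]

    # -- calsequestrin and SR Ca
    dydt[R.S_CSQN] = (p[P.P_KON_CSQN] * Ca_sr
                      * (p[P.P_BMAX_CSQN] - y[R.S_CSQN])
                      - p[P.P_KOFF_CSQN] * y[R.S_CSQN])
    Vmyo = p[P.P_VMYO]
    Vsr = p[P.P_VSR]
    Vsl = p[P.P_VSL]
    Vjunc = p[P.P_VJUNC]
    dydt[R.S_CA_SR] = (cur[C_J_SERCA]
                       - (cur[C_J_SRLEAK] * Vmyo / Vsr + cur[C_J_SRCAREL])
                       - dydt[R.S_CSQN])

    # -- Na concentrations
    Cmem = p[P.P_CMEM]
    Frdy = p[P.P_FRDY]
    I_Na_tot_junc = (cur[C_I_NA_JUNC] + cur[C_I_NAL_JUNC]
                     + cur[C_I_NABK_JUNC] + 3.0 * cur[C_I_NCX_JUNC]
                     + 3.0 * cur[C_I_NAK_JUNC] + cur[C_I_CANA_JUNC])
    I_Na_tot_sl = (cur[C_I_NA_SL] + cur[C_I_NAL_SL]
                   + cur[C_I_NABK_SL] + 3.0 * cur[C_I_NCX_SL]
                   + 3.0 * cur[C_I_NAK_SL] + cur[C_I_CANA_SL])
    J_na_juncsl = p[P.P_J_NA_JUNCSL]
    J_na_slmyo = p[P.P_J_NA_SLMYO]
    dydt[R.S_NAJ] = (-I_Na_tot_junc * Cmem / (Vjunc * Frdy)
                     + J_na_juncsl / Vjunc * (y[R.S_NASL] - y[R.S_NAJ])
                     - dydt[R.S_NABJ])
    dydt[R.S_NASL] = (-I_Na_tot_sl * Cmem / (Vsl * Frdy)
                      + J_na_juncsl / Vsl * (y[R.S_NAJ] - y[R.S_NASL])
                      + J_na_slmyo / Vsl * (y[R.S_NAI] - y[R.S_NASL])
                      - dydt[R.S_NABSL])
    dydt[R.S_NAI] = J_na_slmyo / Vmyo * (y[R.S_NASL] - y[R.S_NAI])

    # -- K concentration: clamped (38-ODE convention of the model)
    dydt[R.S_KI] = 0.0

    # -- Ca concentrations (with the two adjusted diffusion fluxes)
    I_Ca_tot_junc = (cur[C_I_CA_JUNC] + cur[C_I_CABK_JUNC]
                     + cur[C_I_PCA_JUNC] - 2.0 * cur[C_I_NCX_JUNC])
    I_Ca_tot_sl = (cur[C_I_CA_SL] + cur[C_I_CABK_SL]
                   + cur[C_I_PCA_SL] - 2.0 * cur[C_I_NCX_SL])
    J_ca_juncsl = p[P.P_J_CA_JUNCSL]
    J_ca_slmyo = p[P.P_J_CA_SLMYO]
    dydt[R.S_CAJ] = (-I_Ca_tot_junc * Cmem / (Vjunc * 2.0 * Frdy)
                     + J_ca_juncsl / Vjunc * (y[R.S_CASL] - Caj)
                     - J_CaB_junction
                     + cur[C_J_SRCAREL] * Vsr / Vjunc
                     + cur[C_J_SRLEAK] * Vmyo / Vjunc)
    dydt[R.S_CASL] = (-I_Ca_tot_sl * Cmem / (Vsl * 2.0 * Frdy)
                      + J_ca_juncsl / Vsl * (Caj - y[R.S_CASL])
                      + J_ca_slmyo / Vsl * (Cai - y[R.S_CASL])
                      - J_CaB_sl)
    dydt[R.S_CAI] = (-cur[C_J_SERCA] * Vsr / Vmyo - J_CaB_cytosol
                     + J_ca_slmyo / Vmyo * (y[R.S_CASL] - Cai))

    # -- membrane potential
    I_K_tot = (cur[C_I_TO] + cur[C_I_KR] + cur[C_I_KS] + cur[C_I_KI]
               - 2.0 * cur[C_I_NAK] + cur[C_I_CAK] + cur[C_I_KP])
    I_Cl_tot = cur[C_I_CLCA] + cur[C_I_CLBK]
    I_Na_tot = I_Na_tot_junc + I_Na_tot_sl
    I_Ca_tot = I_Ca_tot_junc + I_Ca_tot_sl
    I_tot = I_Na_tot + I_Cl_tot + I_Ca_tot + I_K_tot
    dydt[R.S_VM] = -I_tot + i_stim

    return dydt


@njit(cache=True)
def nhs_zmax(nhs, lam):
    """Maximal steady-state available-site fraction z_max at stretch lam."""
    Ca50 = nhs[P.NP_CA50_REF] * (1.0 + nhs[P.NP_BETA_1] * (lam - 1.0))
    CaTRPN50 = (nhs[P.NP_CA_TRPN_MAX] * Ca50
                / (Ca50 + (nhs[P.NP_K_REFOFF] / nhs[P.NP_K_ON])
                   * (1.0 - (1.0 + nhs[P.NP_BETA_0] * (lam - 1.0))
                      / (2.0 * nhs[P.NP_GAMMA_TRPN]))))
    n = nhs[P.NP_N_HILL]
    nr = nhs[P.NP_N_REL]
    Kz = nhs[P.NP_K_Z]
    zp = nhs[P.NP_Z_P]
    a0 = nhs[P.NP_ALPHA_0]
    ar1 = nhs[P.NP_ALPHA_R1]
    ar2 = nhs[P.NP_ALPHA_R2]
    zp_nr = zp ** nr
    Kz_nr = Kz ** nr
    denom = zp_nr + Kz_nr
    K1 = ar2 * nr * zp ** (nr - 1.0) * Kz_nr / denom ** 2
    K2 = ar2 * (zp_nr / denom) * (1.0 - nr * Kz_nr / denom)
    G = a0 * (nhs[P.NP_CA_TRPN_MAX] / CaTRPN50) ** n
    return (G - K2) / (ar1 + K1 + G), CaTRPN50


@njit(cache=True)
def nhs_tension(nhs_y, nhs, lam, dlam):
    """Active tension [kPa] from the NHS state at stretch lam."""
    z_max, _ = nhs_zmax(nhs, lam)
    T0 = (nhs[P.NP_T_REF] * (1.0 + nhs[P.NP_BETA_0] * (lam - 1.0))
          * nhs_y[1] / z_max)
    Q = nhs_y[2] + nhs_y[3] + nhs_y[4]
    a = nhs[P.NP_A_XB]
    if Q < 0.0:
        return T0 * (a * Q + 1.0) / (1.0 - Q)
    return T0 * (1.0 + (a + 2.0) * Q) / (1.0 + Q)


@njit(cache=True)
def nhs_derivs(nhs_y, nhs, ca_uM, lam, dlam):
    """d/dt [per ms] of (Ca_TRPN, z, Q1, Q2, Q3); native NHS rates are 1/s."""
    dy = np.zeros(5)
    T = nhs_tension(nhs_y, nhs, lam, dlam)
    koff = nhs[P.NP_K_REFOFF] * (1.0 - T / (nhs[P.NP_GAMMA_TRPN]
                                            * nhs[P.NP_T_REF]))
    if koff < 0.0:
        koff = 0.0
    dy[0] = (nhs[P.NP_K_ON] * ca_uM * (nhs[P.NP_CA_TRPN_MAX] - nhs_y[0])
             - koff * nhs_y[0])
    z_max, CaTRPN50 = nhs_zmax(nhs, lam)
    z = nhs_y[1]
    nr = nhs[P.NP_N_REL]
    dy[1] = (nhs[P.NP_ALPHA_0] * (nhs_y[0] / CaTRPN50) ** nhs[P.NP_N_HILL]
             * (1.0 - z)
             - nhs[P.NP_ALPHA_R1] * z
             - nhs[P.NP_ALPHA_R2] * z ** nr / (z ** nr + nhs[P.NP_K_Z] ** nr))
    dy[2] = nhs[P.NP_A1] * dlam - nhs[P.NP_ALPHA_1] * nhs_y[2]
    dy[3] = nhs[P.NP_A2] * dlam - nhs[P.NP_ALPHA_2] * nhs_y[3]
    dy[4] = nhs[P.NP_A3] * dlam - nhs[P.NP_ALPHA_3] * nhs_y[4]
    return dy * 1e-3  # 1/s -> 1/ms


@njit(cache=True)
def full_rhs(y, p, f, nhs, i_stim, lam, dlam):
    """Coupled GPB + NHS right-hand side (one-way Ca coupling)."""
    dydt = gpb_derivs(y, p, f, i_stim)
    ca_uM = y[R.S_CAI] * 1e3
    dnhs = nhs_derivs(y[R.S_CA_TRPN:R.S_CA_TRPN + 5], nhs, ca_uM, lam, dlam)
    dydt[R.S_CA_TRPN:R.S_CA_TRPN + 5] = dnhs
    return dydt
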