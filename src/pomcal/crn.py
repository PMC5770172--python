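"""Courtemanche-Ramirez-Nattel (CRN) human atrial action-potential model.

21-state Hodgkin-Huxley-type ODE system: 12 gating variables, membrane
potential, intracellular Na+/K+/Ca2+ and the two sarcoplasmic-reticulum Ca2+
compartments.  The right-hand side is compiled with numba; all maximal current
magnitudes enter through dimensionless multipliers so populations of models
can be built by rescaling them.

State vector layout (index -> variable):
    0  V      membrane potential (mV)
    1  m      I_Na activation
    2  h      I_Na fast inactivation
    3  j      I_Na slow inactivation
    4  oa     I_to activation
    5  oi     I_to inactivation
    6  ua     I_Kur activation
    7  ui     I_Kur inactivation
    8  xr     I_Kr activation
    9  xs     I_Ks activation
    10 d      I_CaL activation
    11 f      I_CaL voltage inactivation
    12 f_Ca   I_CaL calcium inactivation
    13 u      Ca2+ release activation
    14 v      Ca2+ release inactivation
    15 w      Ca2+ release voltage inactivation
    16 Na_i   intracellular Na+ (mM)
    17 K_i    intracellular K+ (mM)
    18 Ca_i   intracellular Ca2+ (mM)
    19 Ca_up  network SR Ca2+ (mM)
    20 Ca_rel junctional SR Ca2+ (mM)

Parameter vector layout (index -> entry):
    0..10  multipliers: gNa, gto, gKur, gKr, gKs, gK1, gCaL,
           INaK_max, INaCa_max, Iup_max, krel
    11     tau_h_scale (multiplier on the I_Na h-gate time constant)
    12     T (K), 13 Na_o (mM), 14 K_o (mM), 15 Ca_o (mM)
    16     stimulus current (pA; 0 outside the stimulus window)
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATES = 21

# Physical constants and cell geometry (original publication values).
R_GAS = 8.3143      # J/(K mol)
FARADAY = 96.4867   # C/mmol
CM = 100.0          # pF
V_I = 13668.0       # um^3
V_UP = 1109.52      # um^3
V_REL = 96.48       # um^3

# Baseline maximal conductances (nS/pF), pump/exchanger magnitudes and SR rates.
G_NA = 7.8
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_K1 = 0.09
G_CAL = 0.12375
G_B_NA = 0.0006744375
G_B_CA = 0.001131
I_NAK_MAX = 0.59933874  # pA/pF
I_NACA_MAX = 1600.0     # pA/pF
I_PCA_MAX = 0.275       # pA/pF
I_UP_MAX = 0.005        # mM/ms
K_REL = 30.0            # 1/ms

K_Q10 = 3.0
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0
KM_NA_I = 10.0
KM_K_O = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

# Default experimental conditions used throughout this package (temperature
# and bath concentrations of the patch-clamp recordings being emulated).
T_DEFAULT = 309.65
NA_O_DEFAULT = 149.42
K_O_DEFAULT = 4.5
CA_O_DEFAULT = 1.8

N_PARAMS = 17


def initial_state() -> np.ndarray:
    """Published CRN resting initial conditions."""
    return np.array([
        -81.18,       # V
        2.908e-3,     # m
        9.649e-1,     # h
        9.775e-1,     # j
        3.043e-2,     # oa
        9.992e-1,     # oi
        4.966e-3,     # ua
        9.986e-1,     # ui
        3.296e-5,     # xr
        1.869e-2,     # xs
        1.367e-4,     # d
        9.996e-1,     # f
        7.755e-1,     # f_Ca
        0.0,          # u
        1.0,          # v
        9.992e-1,     # w
        11.17,        # Na_i
        139.0,        # K_i
        1.013e-4,     # Ca_i
        1.488,        # Ca_up
        1.488,        # Ca_rel
    ])


def pack_params(multipliers, tau_h_scale=1.0,
                temperature=T_DEFAULT, Na_o=NA_O_DEFAULT,
                K_o=K_O_DEFAULT, Ca_o=CA_O_DEFAULT,
                stim_current=0.0) -> np.ndarray:
    p = np.empty(N_PARAMS)
    p[0:11] = np.asarray(multipliers, dtype=float)
    p[11] = tau_h_scale
    p[12] = temperature
    p[13] = Na_o
    p[14] = K_o
    p[15] = Ca_o
    p[16] = stim_current
    return p


@njit(cache=True, fastmath=False)
def rhs(t, y, p):  # noqa: C901 - one flat function keeps the jit simple
    V = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    oa = y[4]
    oi = y[5]
    ua = y[6]
    ui = y[7]
    xr = y[8]
    xs = y[9]
    d = y[10]
    f = y[11]
    f_Ca = y[12]
    u = y[13]
    v = y[14]
    w = y[15]
    Na_i = y[16]
    K_i = y[17]
    Ca_i = y[18]
    Ca_up = y[19]
    Ca_rel = y[20]

    s_gNa = p[0]
    s_gto = p[1]
    s_gKur = p[2]
    s_gKr = p[3]
    s_gKs = p[4]
    s_gK1 = p[5]
    s_gCaL = p[6]
    s_INaK = p[7]
    s_INaCa = p[8]
    s_Iup = p[9]
    s_krel = p[10]
    tau_h_scale = p[11]
    T = p[12]
    Na_o = p[13]
    K_o = p[14]
    Ca_o = p[15]
    i_st = p[16]

    rtf = R_GAS * T / FARADAY

    # Reversal potentials
    E_Na = rtf * np.log(Na_o / Na_i)
    E_K = rtf * np.log(K_o / K_i)
    E_Ca = 0.5 * rtf * np.log(Ca_o / Ca_i)

    # Fast Na+ current
    i_Na = CM * s_gNa * G_NA * m ** 3 * h * j * (V - E_Na)

    if abs(V + 47.13) < 1e-10:
        alpha_m = 3.2
    else:
        alpha_m = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    beta_m = 0.08 * np.exp(-V / 11.0)

    if V < -40.0:
        alpha_h = 0.135 * np.exp((V + 80.0) / -6.8)
        beta_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        alpha_j = ((-1.2714e5 * np.exp(0.2444 * V)
                    - 3.474e-5 * np.exp(-0.04391 * V))
                   * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        beta_j = (0.1212 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))))
    else:
        alpha_h = 0.0
        beta_h = 1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1)))
        alpha_j = 0.0
        beta_j = (0.3 * np.exp(-2.535e-7 * V)
                  / (1.0 + np.exp(-0.1 * (V + 32.0))))

    m_inf = alpha_m / (alpha_m + beta_m)
    tau_m = 1.0 / (alpha_m + beta_m)
    h_inf = alpha_h / (alpha_h + beta_h)
    tau_h = tau_h_scale / (alpha_h + beta_h)
    j_inf = alpha_j / (alpha_j + beta_j)
    tau_j = 1.0 / (alpha_j + beta_j)

    # Transient outward K+ current
    i_to = CM * s_gto * G_TO * oa ** 3 * oi * (V - E_K)
    alpha_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    beta_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((alpha_oa + beta_oa) * K_Q10)
    oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    alpha_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    beta_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / ((alpha_oi + beta_oi) * K_Q10)
    oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))

    # Ultra-rapid delayed rectifier K+ current (voltage-dependent conductance)
    g_Kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    i_Kur = CM * s_gKur * g_Kur * ua ** 3 * ui * (V - E_K)
    alpha_ua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    beta_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((alpha_ua + beta_ua) * K_Q10)
    ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    alpha_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    beta_ui = np.exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((alpha_ui + beta_ui) * K_Q10)
    ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))

    # Rapid delayed rectifier
    i_Kr = (CM * s_gKr * G_KR * xr * (V - E_K)
            / (1.0 + np.exp((V + 15.0) / 22.4)))
    if abs(V + 14.1) < 1e-10:
        alpha_xr = 0.0015
    else:
        alpha_xr = (0.0003 * (V + 14.1)
                    / (1.0 - np.exp(-(V + 14.1) / 5.0)))
    if abs(V - 3.3328) < 1e-10:
        beta_xr = 3.7836118e-4
    else:
        beta_xr = (7.3898e-5 * (V - 3.3328)
                   / (np.exp((V - 3.3328) / 5.1237) - 1.0))
    tau_xr = 1.0 / (alpha_xr + beta_xr)
    xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))

    # Slow delayed rectifier
    i_Ks = CM * s_gKs * G_KS * xs ** 2 * (V - E_K)
    if abs(V - 19.9) < 1e-10:
        alpha_xs = 0.00068
        beta_xs = 0.000315
    else:
        alpha_xs = (4e-5 * (V - 19.9)
                    / (1.0 - np.exp(-(V - 19.9) / 17.0)))
        beta_xs = (3.5e-5 * (V - 19.9)
                   / (np.exp((V - 19.9) / 9.0) - 1.0))
    tau_xs = 0.5 / (alpha_xs + beta_xs)
    xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))

    # Inward rectifier
    i_K1 = (CM * s_gK1 * G_K1 * (V - E_K)
            / (1.0 + np.exp(0.07 * (V + 80.0))))

    # L-type Ca2+ current
    i_CaL = CM * s_gCaL * G_CAL * d * f * f_Ca * (V - 65.0)
    if abs(V + 10.0) < 1e-10:
        tau_d = 4.579 / (1.0 + np.exp(-(V + 10.0) / 6.24))
    else:
        tau_d = ((1.0 - np.exp(-(V + 10.0) / 6.24))
                 / (0.035 * (V + 10.0) * (1.0 + np.exp(-(V + 10.0) / 6.24))))
    d_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
    f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    f_Ca_inf = 1.0 / (1.0 + Ca_i / 0.00035)

    # Na+/K+ pump
    sigma = (np.exp(Na_o / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * FARADAY * V / (R_GAS * T))
                   + 0.0365 * sigma * np.exp(-FARADAY * V / (R_GAS * T)))
    i_NaK = (CM * s_INaK * I_NAK_MAX * f_NaK
             * (1.0 / (1.0 + (KM_NA_I / Na_i) ** 1.5))
             * (K_o / (K_o + KM_K_O)))

    # Na+/Ca2+ exchanger
    expg = np.exp(GAMMA_NACA * FARADAY * V / (R_GAS * T))
    expg1 = np.exp((GAMMA_NACA - 1.0) * FARADAY * V / (R_GAS * T))
    i_NaCa = (CM * s_INaCa * I_NACA_MAX
              * (expg * Na_i ** 3 * Ca_o - expg1 * Na_o ** 3 * Ca_i)
              / ((KM_NA ** 3 + Na_o ** 3) * (KM_CA + Ca_o)
                 * (1.0 + K_SAT * expg1)))

    # Background and pump currents
    i_B_Na = CM * G_B_NA * (V - E_Na)
    i_B_Ca = CM * G_B_CA * (V - E_Ca)
    i_PCa = CM * I_PCA_MAX * Ca_i / (0.0005 + Ca_i)

    # SR Ca2+ handling
    i_rel = s_krel * K_REL * u ** 2 * v * w * (Ca_rel - Ca_i)
    i_tr = (Ca_up - Ca_rel) / TAU_TR
    i_up = s_Iup * I_UP_MAX / (1.0 + K_UP / Ca_i)
    i_up_leak = s_Iup * I_UP_MAX * Ca_up / CA_UP_MAX

    Fn = 1e3 * (1e-15 * V_REL * i_rel
                - (1e-15 / (2.0 * FARADAY)) * (0.5 * i_CaL - 0.2 * i_NaCa))
    u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    if abs(V - 7.9) < 1e-10:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        tau_w = (6.0 * (1.0 - np.exp(-(V - 7.9) / 5.0))
                 / ((1.0 + 0.3 * np.exp(-(V - 7.9) / 5.0)) * (V - 7.9)))
    w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))

    dy = np.empty(N_STATES)
    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_B_Na + i_B_Ca
             + i_NaK + i_PCa + i_NaCa + i_CaL)
    dy[0] = -(i_ion + i_st) / CM
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (oa_inf - oa) / tau_oa
    dy[5] = (oi_inf - oi) / tau_oi
    dy[6] = (ua_inf - ua) / tau_ua
    dy[7] = (ui_inf - ui) / tau_ui
    dy[8] = (xr_inf - xr) / tau_xr
    dy[9] = (xs_inf - xs) / tau_xs
    dy[10] = (d_inf - d) / tau_d
    dy[11] = (f_inf - f) / tau_f
    dy[12] = (f_Ca_inf - f_Ca) / TAU_F_CA
    dy[13] = (u_inf - u) / TAU_U
    dy[14] = (v_inf - v) / tau_v
    dy[15] = (w_inf - w) / tau_w
    dy[16] = (-3.0 * i_NaK - (3.0 * i_NaCa + i_B_Na + i_Na)) / (V_I * FARADAY)
    dy[17] = (2.0 * i_NaK
              - (i_K1 + i_to + i_Kur + i_Kr + i_Ks)) / (V_I * FARADAY)
    B1 = ((2.0 * i_NaCa - (i_PCa + i_CaL + i_B_Ca)) / (2.0 * V_I * FARADAY)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    B2 = (1.0 + TRPN_MAX * KM_TRPN / (Ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Ca_i + KM_CMDN) ** 2)
    dy[18] = B1 / B2
    dy[19] = i_up - (i_up_leak + i_tr * V_REL / V_UP)
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                               / (Ca_rel + KM_CSQN) ** 2)
    return dy


def dvdt(t: float, y: np.ndarray, p: np.ndarray) -> float:
    """Membrane-potential derivative (mV/ms) from the model right-hand side."""
    return rhs(t, y, p)[0]
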