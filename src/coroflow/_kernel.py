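"""Compiled right-hand side of the closed-loop circuit ODE system.

The full parameter set is flattened into one float64 vector (see the ``I*``
index constants) so the derivative function can be JIT-compiled with numba.
If numba is unavailable the same functions run as plain Python.

State vector (length NY = 18):
    0  V_LV        left-ventricular volume [mL]
    1  V_LA        left-atrial volume [mL]
    2  P_ao        aortic-root pressure (C_ao) [mmHg]
    3  P_SAC       systemic arteries/veins pressure (C_SAC) [mmHg]
    4  P_PVC       pulmonary vein/capillary pressure (C_PVC) [mmHg]
    5  P_PA        pulmonary arterial pressure (C_PA) [mmHg]
    6  Q_AV        aortic-valve flow (inductive state) [mL/s]
    7  Q_MV        mitral-valve flow (inductive state) [mL/s]
    8  Q_AR        aortic regurgitant flow, aorta -> LV [mL/s]
    9  Q_MR        mitral regurgitant flow, LV -> LA [mL/s]
    10 Q_PV        pulmonary-vein inductor flow, into LA [mL/s]
    11 Q_PC        pulmonary-capillary inductor flow [mL/s]
    12.. per coronary branch (LAD, LCX, RCA): P_p (proximal capacitor, to
         ground) and U_m (medial capacitor charge pressure, referenced to the
         intramyocardial source so that P_m = U_m + P_im)
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


# --- parameter vector indices ------------------------------------------------
IT = 0
ITEJ = 1
# LV elastance: Emax, Emin, m1, m2, tau1*T, tau2*T, V0, normalisation
ILV = 2
# LA elastance: same 8 slots, then activation onset time
ILA = 10
ILA_ONSET = 18
# valves: inertial (B) and convective (K) coefficients
IAV_B, IAV_K = 19, 20
IMV_B, IMV_K = 21, 22
IAR_B, IAR_K, IAR_ON = 23, 24, 25
IMR_B, IMR_K, IMR_ON = 26, 27, 28
ILEAK_R, ILEAK_ON = 29, 30
# systemic
IR_AO, IR_SV, IR_SA, IR_UB, IR_PDA, IC_AO, IC_SAC, IP_CV0 = 31, 32, 33, 34, 35, 36, 37, 38
# pulmonary
IL_PV, IL_PC, IR_PV, IR_PVC, IR_PC, IR_PA, IC_PVC, IC_PA, IQ_MPV = (
    39, 40, 41, 42, 43, 44, 45, 46, 47)
# coronary branches: 6 slots each (R_p, R_m, R_d, C_p, C_m, im_scale)
ICOR0 = 48
# smooth-diode regularisation: gradient half-window [mmHg], closed resistance
IDELTA, IRCLOSED = 66, 67
NP = 68

NY = 18
ICORSTATE0 = 12

SIGNAL_NAMES = (
    "P_LV", "P_LA", "P_ao_root", "P_SAC", "P_PVC", "P_PA",
    "V_LV", "V_LA",
    "Q_AV", "Q_MV", "Q_AR", "Q_MR", "Q_leak",
    "Q_upper_body", "Q_descending", "Q_pulmonary_source", "Q_LA_inflow",
    "q_LAD", "q_LCX", "q_RCA",
    "q_out_LAD", "q_out_LCX", "q_out_RCA",
    "E_LV",
)
NSIG = len(SIGNAL_NAMES)


@njit(cache=True)
def hill_product(tc, tau1, tau2, m1, m2):
    """Un-normalised double-Hill activation shape at cycle time tc >= 0."""
    if tc <= 0.0:
        return 0.0
    g1 = (tc / tau1) ** m1
    g2 = (tc / tau2) ** m2
    return (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2))


@njit(cache=True)
def _elastance(tc, p, base):
    return (p[base] - p[base + 1]) * hill_product(
        tc, p[base + 4], p[base + 5], p[base + 2], p[base + 3]
    ) / p[base + 7] + p[base + 1]


@njit(cache=True)
def _valve_dq(dp, q, B, K, delta, rclosed):
    s = 0.5 * (1.0 + math.tanh(dp / delta))
    return (dp - K * q * abs(q) - (1.0 - s) * rclosed * q) / B


@njit(cache=True)
def rhs(t, y, p):
    dy = np.zeros(NY)
    T = p[IT]
    tc = t % T

    E_lv = _elastance(tc, p, ILV)
    P_lv = E_lv * (y[0] - p[ILV + 6])
    tla = (tc - p[ILA_ONSET]) % T
    E_la = _elastance(tla, p, ILA)
    P_la = E_la * (y[1] - p[ILA + 6])

    P_ao = y[2]
    P_sac = y[3]
    delta = p[IDELTA]
    rclosed = p[IRCLOSED]

    q_av = y[6]
    q_mv = y[7]
    dy[6] = _valve_dq(P_lv - P_ao, q_av, p[IAV_B], p[IAV_K], delta, rclosed)
    dy[7] = _valve_dq(P_la - P_lv, q_mv, p[IMV_B], p[IMV_K], delta, rclosed)

    q_ar = 0.0
    if p[IAR_ON] > 0.5:
        q_ar = y[8]
        dy[8] = _valve_dq(P_ao - P_lv, q_ar, p[IAR_B], p[IAR_K], delta, rclosed)
    q_mr = 0.0
    if p[IMR_ON] > 0.5:
        q_mr = y[9]
        dy[9] = _valve_dq(P_lv - P_la, q_mr, p[IMR_B], p[IMR_K], delta, rclosed)
    q_leak = 0.0
    if p[ILEAK_ON] > 0.5:
        q_leak = (P_lv - P_ao) / p[ILEAK_R]  # signed, positive toward aorta

    q_sys = (P_ao - P_sac) / (p[IR_AO] + p[IR_PDA])
    q_ub = (P_ao - p[IP_CV0]) / p[IR_UB]
    q_out_sys = (P_sac - p[IP_CV0]) / (p[IR_SA] + p[IR_SV])

    q_cor_in = 0.0
    for b in range(3):
        base = ICOR0 + 6 * b
        sb = ICORSTATE0 + 2 * b
        P_im = p[base + 5] * P_lv
        P_p = y[sb]
        P_m = y[sb + 1] + P_im
        q_in = (P_ao - P_p) / p[base]
        q_m = (P_p - P_m) / p[base + 1]
        q_o = (P_m - p[IP_CV0]) / p[base + 2]
        dy[sb] = (q_in - q_m) / p[base + 3]
        dy[sb + 1] = (q_m - q_o) / p[base + 4]
        q_cor_in += q_in

    # imposed pulmonary-valve inflow: half-sine over the ejection window whose
    # cycle mean equals Q_MPV
    tej = p[ITEJ]
    if tc < tej:
        q_src = 0.5 * math.pi * p[IQ_MPV] * (T / tej) * math.sin(math.pi * tc / tej)
    else:
        q_src = 0.0
    dy[11] = (y[5] - y[4] - (p[IR_PA] + p[IR_PC]) * y[11]) / p[IL_PC]
    dy[10] = (y[4] - P_la - (p[IR_PVC] + p[IR_PV]) * y[10]) / p[IL_PV]
    dy[5] = (q_src - y[11]) / p[IC_PA]
    dy[4] = (y[11] - y[10]) / p[IC_PVC]

    dy[0] = q_mv - q_av + q_ar - q_mr - q_leak
    dy[1] = y[10] - q_mv + q_mr
    dy[2] = (q_av + q_leak - q_ar - q_sys - q_ub - q_cor_in) / p[IC_AO]
    dy[3] = (q_sys - q_out_sys) / p[IC_SAC]
    return dy


@njit(cache=True)
def outputs_grid(ts, Y, p):
    """Algebraic signals on a trajectory grid; rows align with ts/Y."""
    n = ts.shape[0]
    out = np.empty((n, NSIG))
    T = p[IT]
    tej = p[ITEJ]
    for i in range(n):
        tc = ts[i] % T
        y = Y[i]
        E_lv = _elastance(tc, p, ILV)
        P_lv = E_lv * (y[0] - p[ILV + 6])
        tla = (tc - p[ILA_ONSET]) % T
        P_la = _elastance(tla, p, ILA) * (y[1] - p[ILA + 6])
        P_ao = y[2]
        P_sac = y[3]
        q_leak = 0.0
        if p[ILEAK_ON] > 0.5:
            q_leak = (P_lv - P_ao) / p[ILEAK_R]
        q_ub = (P_ao - p[IP_CV0]) / p[IR_UB]
        q_sys = (P_ao - P_sac) / (p[IR_AO] + p[IR_PDA])
        if tc < tej:
            q_src = 0.5 * math.pi * p[IQ_MPV] * (T / tej) * math.sin(math.pi * tc / tej)
        else:
            q_src = 0.0
        out[i, 0] = P_lv
        out[i, 1] = P_la
        out[i, 2] = P_ao
        out[i, 3] = P_sac
        out[i, 4] = y[4]
        out[i, 5] = y[5]
        out[i, 6] = y[0]
        out[i, 7] = y[1]
        out[i, 8] = y[6]
        out[i, 9] = y[7]
        out[i, 10] = y[8] if p[IAR_ON] > 0.5 else 0.0
        out[i, 11] = y[9] if p[IMR_ON] > 0.5 else 0.0
        out[i, 12] = q_leak
        out[i, 13] = q_ub
        out[i, 14] = q_sys
        out[i, 15] = q_src
        out[i, 16] = y[10]
        for b in range(3):
            base = ICOR0 + 6 * b
            sb = ICORSTATE0 + 2 * b
            P_im = p[base + 5] * P_lv
            P_m = y[sb + 1] + P_im
            out[i, 17 + b] = (P_ao - y[sb]) / p[base]
            out[i, 20 + b] = (P_m - p[IP_CV0]) / p[base + 2]
        out[i, 23] = E_lv
    return out
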