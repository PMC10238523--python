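"""Component-level physics: elastance chambers, valve laws, coronary branch
ODEs, and assembly of the full system derivative.

The heavy lifting during integration happens in the flattened kernel
(:mod:`coroflow._kernel`); the functions here are the documented, unit-aware
surface used directly in analysis and tests, plus the packing step that turns
a :class:`~coroflow.parameters.ModelParameters` into the kernel's parameter
vector.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernel
from ._kernel import NSIG, NY, SIGNAL_NAMES, hill_product  # noqa: F401  (re-export)
from .errors import DomainError
from .parameters import (
    BRANCHES,
    ChamberElastanceParams,
    CoronaryBranchParameters,
    ModelParameters,
    ValveParameters,
)

__all__ = [
    "elastance",
    "elastance_normalization",
    "chamber_pressure",
    "valve_pressure_gradient",
    "coronary_branch_derivatives",
    "coronary_branch_steady_flow",
    "system_derivatives",
    "pack_parameters",
    "SIGNAL_NAMES",
]

#: half-window of the smooth valve diode [mmHg] (full blending window 0.1 mmHg)
DIODE_DELTA = 0.05
#: effective resistance of a closed valve path [mmHg s/mL]
DIODE_R_CLOSED = 1000.0


@lru_cache(maxsize=256)
def _normalization(tau1: float, tau2: float, m1: float, m2: float, T: float) -> float:
    """Max over one cycle of the raw double-Hill product (grid + local refine)."""
    ts = np.linspace(0.0, T, 2049)
    vals = np.array([hill_product(t, tau1, tau2, m1, m2) for t in ts])
    k = int(np.argmax(vals))
    lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, len(ts) - 1)]
    res = minimize_scalar(
        lambda t: -hill_product(t, tau1, tau2, m1, m2),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(max(-res.fun, vals[k]))


def elastance_normalization(params: ChamberElastanceParams, T: float) -> float:
    """Normalisation constant N so that max_t E(t) = E_max exactly."""
    return _normalization(params.tau1 * T, params.tau2 * T, params.m1, params.m2, T)


def elastance(t, params: ChamberElastanceParams, T: float):
    """Double-Hill time-varying elastance E(t) [mmHg/mL].

    ``E(t) = (E_max - E_min) * [g1/(1+g1)] * [1/(1+g2)] / N + E_min`` with
    ``g1 = (t/tau1)^m1``, ``g2 = (t/tau2)^m2`` and N the cycle maximum of the
    bracketed product. ``t`` is time since activation onset, taken modulo T;
    scalar or array."""
    N = elastance_normalization(params, T)
    tau1, tau2 = params.tau1 * T, params.tau2 * T
    tc = np.asarray(t, dtype=float) % T
    shape = np.where(
        tc > 0,
        (lambda g1, g2: (g1 / (1.0 + g1)) / (1.0 + g2))(
            (np.maximum(tc, 1e-300) / tau1) ** params.m1,
            (np.maximum(tc, 1e-300) / tau2) ** params.m2,
        ),
        0.0,
    )
    E = (params.E_max - params.E_min) * shape / N + params.E_min
    return float(E) if np.isscalar(t) else E


def chamber_pressure(V, E, V0: float):
    """Elastance chamber pressure P = E * (V - V0) [mmHg]."""
    return E * (V - V0)


def valve_pressure_gradient(Q, dQdt, valve: ValveParameters, rho: float = 1050.0):
    """Net transvalvular pressure drop [mmHg] for flow Q [mL/s].

    ``dP = B * dQ/dt + K * Q * |Q|`` where B is the valve's inertial
    coefficient and K the convective (energy-loss) coefficient derived from
    ELCo and blood density. The diode behaviour (no flow against an adverse
    gradient) lives in the system assembly, not here."""
    if valve.ELCo <= 0:
        raise DomainError("ELCo must be positive")
    K = valve.convective_coeff(rho)
    Q = np.asarray(Q, dtype=float)
    return valve.inertance_coeff * np.asarray(dQdt, dtype=float) + K * Q * np.abs(Q)


class BranchDerivatives(NamedTuple):
    dP_p_dt: float
    dU_m_dt: float
    q_in: float
    q_m: float
    q_out: float


def coronary_branch_derivatives(
    P_in: float,
    P_out: float,
    P_im: float,
    dPim_dt: float,
    state: tuple[float, float],
    params: CoronaryBranchParameters,
) -> BranchDerivatives:
    """Coronary branch circuit derivatives and flows.

    ``state = (P_p, U_m)`` where ``P_p`` is the proximal capacitor pressure
    (to ground) and ``U_m`` the medial capacitor charge pressure referenced to
    the intramyocardial source, so the medial node sits at
    ``P_m = U_m + P_im``. Flows: ``q_in = (P_in - P_p)/R_p``,
    ``q_m = (P_p - P_m)/R_m``, ``q_out = (P_m - P_out)/R_d``; the capacitor
    balances are ``C_p dP_p/dt = q_in - q_m`` and
    ``C_m d(P_m - P_im)/dt = q_m - q_out``. ``dPim_dt`` is accepted for
    interface completeness (the charge balance is expressed in U_m, which
    already absorbs it)."""
    P_p, U_m = state
    P_m = U_m + P_im
    q_in = (P_in - P_p) / params.R_p
    q_m = (P_p - P_m) / params.R_m
    q_out = (P_m - P_out) / params.R_d
    return BranchDerivatives(
        dP_p_dt=(q_in - q_m) / params.C_p,
        dU_m_dt=(q_m - q_out) / params.C_m,
        q_in=q_in, q_m=q_m, q_out=q_out,
    )


def coronary_branch_steady_flow(
    P_in: float, P_out: float, params: CoronaryBranchParameters
) -> float:
    """Closed-form steady flow of the resistive chain under constant pressures.

    With constant imposed pressures the capacitors carry no current and
    ``q_in = q_m = q_out = (P_in - P_out) / (R_p + R_m + R_d)``. Serves as the
    independent oracle for the branch ODE solver."""
    return (P_in - P_out) / params.R_total


def _valve_coeffs(valve: ValveParameters | None, rho: float) -> tuple[float, float, float]:
    if valve is None:
        return 1.0, 0.0, 0.0
    return valve.inertance_coeff, valve.convective_coeff(rho), 1.0


def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten a ModelParameters into the kernel's float64 parameter vector."""
    p = np.zeros(_kernel.NP)
    T = params.T
    p[_kernel.IT] = T
    p[_kernel.ITEJ] = params.T_EJ

    for base, ch in ((_kernel.ILV, params.lv), (_kernel.ILA, params.la)):
        p[base] = ch.E_max
        p[base + 1] = ch.E_min
        p[base + 2] = ch.m1
        p[base + 3] = ch.m2
        p[base + 4] = ch.tau1 * T
        p[base + 5] = ch.tau2 * T
        p[base + 6] = ch.V0
        p[base + 7] = elastance_normalization(ch, T)
    p[_kernel.ILA_ONSET] = params.la.activation_delay % T

    rho = params.rho
    p[_kernel.IAV_B], p[_kernel.IAV_K], _ = _valve_coeffs(params.valve_aortic, rho)
    p[_kernel.IMV_B], p[_kernel.IMV_K], _ = _valve_coeffs(params.valve_mitral, rho)
    p[_kernel.IAR_B], p[_kernel.IAR_K], p[_kernel.IAR_ON] = _valve_coeffs(
        params.valve_aortic_regurgitant, rho)
    p[_kernel.IMR_B], p[_kernel.IMR_K], p[_kernel.IMR_ON] = _valve_coeffs(
        params.valve_mitral_regurgitant, rho)
    if params.leak_resistance is not None:
        p[_kernel.ILEAK_R] = params.leak_resistance
        p[_kernel.ILEAK_ON] = 1.0
    else:
        p[_kernel.ILEAK_R] = 1.0

    s = params.systemic
    p[_kernel.IR_AO] = s.R_ao
    p[_kernel.IR_SV] = s.R_SV
    p[_kernel.IR_SA] = s.R_SA
    p[_kernel.IR_UB] = s.R_ub
    p[_kernel.IR_PDA] = s.R_pda
    p[_kernel.IC_AO] = s.C_ao
    p[_kernel.IC_SAC] = s.C_SAC
    p[_kernel.IP_CV0] = s.P_CV0

    pm = params.pulmonary
    p[_kernel.IL_PV] = pm.L_PV
    p[_kernel.IL_PC] = pm.L_PC
    p[_kernel.IR_PV] = pm.R_PV
    p[_kernel.IR_PVC] = pm.R_PVC
    p[_kernel.IR_PC] = pm.R_PC
    p[_kernel.IR_PA] = pm.R_PA
    p[_kernel.IC_PVC] = pm.C_PVC
    p[_kernel.IC_PA] = pm.C_PA
    p[_kernel.IQ_MPV] = pm.Q_MPV

    for b, name in enumerate(BRANCHES):
        cb = params.coronary[name]
        base = _kernel.ICOR0 + 6 * b
        p[base] = cb.R_p
        p[base + 1] = cb.R_m
        p[base + 2] = cb.R_d
        p[base + 3] = cb.C_p
        p[base + 4] = cb.C_m
        p[base + 5] = cb.im_pressure_scale

    p[_kernel.IDELTA] = DIODE_DELTA
    p[_kernel.IRCLOSED] = DIODE_R_CLOSED
    return p


def system_derivatives(t: float, state: np.ndarray, params: ModelParameters | np.ndarray):
    """Full closed-loop derivative dy/dt at time t.

    Accepts either a ModelParameters (packed on the fly) or an already packed
    parameter vector. See :mod:`coroflow._kernel` for the state layout."""
    p = params if isinstance(params, np.ndarray) else pack_parameters(params)
    y = np.asarray(state, dtype=float)
    if y.shape != (NY,):
        raise DomainError(f"state must have length {NY}")
    dy = _kernel.rhs(float(t), y, p)
    if not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        names = ("LV volume", "LA volume", "aortic root", "systemic bed",
                 "pulmonary venous bed", "pulmonary artery", "aortic valve",
                 "mitral valve", "aortic regurgitant path", "mitral regurgitant path",
                 "pulmonary vein inductor", "pulmonary capillary inductor",
                 "LAD proximal", "LAD medial", "LCX proximal", "LCX medial",
                 "RCA proximal", "RCA medial")
        from .errors import SimulationError

        raise SimulationError(f"non-finite derivative in component: {names[bad]}")
    return dy
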