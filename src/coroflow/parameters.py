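"""Derivation of every circuit element from non-invasive measurements.

The derivation chain is:

* mean arterial pressure from cuff pressures and heart rate,
  ``MAP = DBP + [1/3 + 0.0012*HR] * (SBP - DBP)``;
* total coronary resistance from the assumption that the coronary bed carries
  4.0% of cardiac output, ``R_total = MAP / (0.04 * CO)``;
* per-branch resistances from a Murray's-law allocation on the proximal
  cross-sectional areas (weights ``sqrt(A)^2.6``), an optional stenosis
  correction ``R * (A_sten/A)^-2``, and a fixed 0.32 / 0.52 / 0.16 split into
  proximal / medial / distal resistors;
* per-branch compliances from an area-proportional share of the per-side
  totals and a fixed 0.11 / 0.89 proximal/medial split;
* valve coefficients from effective orifice areas through the energy-loss
  coefficient ``ELCo = EOA*A / (A - EOA)``.

Everything else (systemic, pulmonary, elastance) is a literature constant or a
tunable initial value; see the per-class docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import DomainError
from .patients import CoronaryAnatomy, PatientMeasurements

__all__ = [
    "BRANCHES",
    "CoronaryBranchParameters",
    "ChamberElastanceParams",
    "ValveParameters",
    "SystemicParameters",
    "PulmonaryParameters",
    "ModelParameters",
    "compute_map",
    "total_coronary_resistance",
    "allocate_branch_resistances",
    "allocate_branch_compliances",
    "energy_loss_coefficient",
    "derive_coronary_branches",
    "build_model_parameters",
]

BRANCHES = ("LAD", "LCX", "RCA")

MMHG_PER_DYN_CM2 = 1.0 / 1333.22
#: proximal/medial/distal resistor split fractions
R_SPLIT = (0.32, 0.52, 0.16)
#: proximal/medial capacitor split fractions
C_SPLIT = (0.11, 0.89)
#: coronary share of cardiac output
CORONARY_FLOW_FRACTION = 0.04
#: Murray's-law exponent on sqrt(area)
MURRAY_EXPONENT = 2.6


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CoronaryBranchParameters:
    """Three-resistor / two-capacitor coronary branch with an intramyocardial source.

    ``im_pressure_scale`` scales the left-ventricular pressure into the
    intramyocardial compression source: 1.0 for the left branches, 0.5 for the
    RCA (no right ventricle is modelled)."""

    R_p: float
    R_m: float
    R_d: float
    C_p: float
    C_m: float
    im_pressure_scale: float = 1.0

    @property
    def R_total(self) -> float:
        return self.R_p + self.R_m + self.R_d

    @property
    def C_total(self) -> float:
        return self.C_p + self.C_m


@dataclass
class ChamberElastanceParams:
    """Double-Hill time-varying elastance parameters; tau1/tau2 are fractions of T."""

    E_max: float
    E_min: float
    m1: float
    m2: float
    tau1: float
    tau2: float
    V0: float
    activation_delay: float = 0.0  # onset time within the cycle [s]

    def __post_init__(self):
        if not (self.E_max > self.E_min > 0):
            raise DomainError("E_max > E_min > 0 required")
        if self.m1 <= 0 or self.m2 <= 0:
            raise DomainError("shape exponents must be positive")
        if not (0 < self.tau1 < self.tau2 < 1):
            raise DomainError("0 < tau1 < tau2 < 1 required")


@dataclass
class ValveParameters:
    """Orifice description of one valve path.

    ``inertance_coeff`` multiplies dQ/dt in the transvalvular pressure-gradient
    law (mmHg s^2/mL); the convective coefficient is derived from ``ELCo`` and
    blood density at assembly time."""

    name: str
    EOA: float
    ELCo: float
    inertance_coeff: float
    direction: str = "forward"  # or "regurgitant"

    def convective_coeff(self, rho: float = 1050.0) -> float:
        """K such that the convective drop is K*Q|Q| in mmHg for Q in mL/s."""
        rho_cgs = rho / 1000.0  # kg/m^3 -> g/cm^3
        return rho_cgs / (2.0 * self.ELCo**2) * MMHG_PER_DYN_CM2


@dataclass
class SystemicParameters:
    """Systemic loop elements. R_ao/R_SV/R_pda and P_CV0 are constants; C_ao,
    C_SAC, R_SA and R_ub start at their initial values and are tuned."""

    R_ao: float = 0.05
    R_SV: float = 0.05
    R_SA: float = 0.8
    R_ub: float = 7.0
    R_pda: float = 0.05
    C_ao: float = 0.5
    C_SAC: float = 2.0
    P_CV0: float = 4.0

    def __post_init__(self):
        for name in ("R_ao", "R_SV", "R_SA", "R_ub", "R_pda", "C_ao", "C_SAC", "P_CV0"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass
class PulmonaryParameters:
    """Pulmonary chain constants plus the tunable mean pulmonary-valve flow."""

    L_PV: float = 5e-4
    L_PC: float = 3e-4
    R_PV: float = 0.002
    R_PVC: float = 0.001
    R_PC: float = 0.21
    R_PA: float = 0.01
    C_PVC: float = 40.0
    C_PA: float = 4.0
    Q_MPV: float = 90.0

    def __post_init__(self):
        for name in ("L_PV", "L_PC", "R_PV", "R_PVC", "R_PC", "R_PA", "C_PVC", "C_PA", "Q_MPV"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass
class ModelParameters:
    """Fully derived circuit element set for one patient state."""

    T: float
    T_EJ: float
    lv: ChamberElastanceParams
    la: ChamberElastanceParams
    valve_aortic: ValveParameters
    valve_mitral: ValveParameters
    systemic: SystemicParameters
    pulmonary: PulmonaryParameters
    coronary: dict[str, CoronaryBranchParameters]
    valve_aortic_regurgitant: Optional[ValveParameters] = None
    valve_mitral_regurgitant: Optional[ValveParameters] = None
    leak_resistance: Optional[float] = None
    rho: float = 1050.0  # kg/m^3
    C_cor_total_left: float = 0.0250
    C_cor_total_right: float = 0.0125
    V_LV_init: float = 130.0
    V_LA_init: float = 60.0


# ---------------------------------------------------------------------------
# Derivation operations
# ---------------------------------------------------------------------------

def compute_map(SBP: float, DBP: float, HR: float) -> float:
    """Mean arterial pressure from cuff pressures and heart rate [mmHg]."""
    if not (SBP >= DBP > 0):
        raise DomainError("require SBP >= DBP > 0")
    if HR <= 0:
        raise DomainError("require HR > 0")
    return DBP + (1.0 / 3.0 + HR * 0.0012) * (SBP - DBP)


def total_coronary_resistance(MAP: float, CO: float) -> float:
    """Total coronary resistance assuming the bed carries 4.0% of CO [mmHg s/mL].

    ``CO`` is in mL/s."""
    if MAP <= 0 or CO <= 0:
        raise DomainError("MAP and CO must be positive")
    return MAP / (CORONARY_FLOW_FRACTION * CO)


def _murray_weight(area: float) -> float:
    return math.sqrt(area) ** MURRAY_EXPONENT  # == area**1.3


def allocate_branch_resistances(
    anatomy: CoronaryAnatomy, R_total: float
) -> dict[str, tuple[float, float, float]]:
    """Split the pooled coronary resistance into per-branch (R_p, R_m, R_d).

    Branch totals follow the Murray's-law allocation (the parallel combination
    of the three branch totals reproduces ``R_total`` exactly); a stenotic
    branch is then penalised by ``alpha**-2`` with ``alpha = A_sten/A``."""
    if R_total <= 0:
        raise DomainError("R_total must be positive")
    weights = {b: _murray_weight(anatomy.area(b)) for b in BRANCHES}
    wsum = sum(weights.values())
    out = {}
    for b in BRANCHES:
        R_branch = wsum / weights[b] * R_total
        alpha = anatomy.stenotic_area(b) / anatomy.area(b)
        if not (0 < alpha <= 1):
            raise DomainError(f"stenosis fraction alpha for {b} must be in (0, 1]")
        R_branch *= alpha**-2
        out[b] = tuple(frac * R_branch for frac in R_SPLIT)
    return out


def allocate_branch_compliances(
    anatomy: CoronaryAnatomy, C_left_total: float, C_right_total: float
) -> dict[str, tuple[float, float]]:
    """Split per-side compliance totals into per-branch (C_p, C_m).

    The left total is shared between LAD and LCX in proportion to area; the
    RCA carries the full right-side total."""
    if C_left_total <= 0 or C_right_total <= 0:
        raise DomainError("compliance totals must be positive")
    left_area = anatomy.A_LAD + anatomy.A_LCX
    shares = {
        "LAD": anatomy.A_LAD / left_area * C_left_total,
        "LCX": anatomy.A_LCX / left_area * C_left_total,
        "RCA": C_right_total,
    }
    return {b: (C_SPLIT[0] * c, C_SPLIT[1] * c) for b, c in shares.items()}


def energy_loss_coefficient(EOA: float, A: float) -> float:
    """Energy-loss coefficient ``EOA*A/(A - EOA)`` [cm^2]; requires EOA < A."""
    if not (0 < EOA < A):
        raise DomainError("require 0 < EOA < A (ELCo diverges at EOA = A)")
    return EOA * A / (A - EOA)


def derive_coronary_branches(
    MAP: float,
    CO: float,
    anatomy: CoronaryAnatomy,
    C_left_total: float,
    C_right_total: float,
) -> dict[str, CoronaryBranchParameters]:
    """Full coronary derivation chain: resistances and compliances per branch."""
    R_total = total_coronary_resistance(MAP, CO)
    rs = allocate_branch_resistances(anatomy, R_total)
    cs = allocate_branch_compliances(anatomy, C_left_total, C_right_total)
    return {
        b: CoronaryBranchParameters(
            R_p=rs[b][0], R_m=rs[b][1], R_d=rs[b][2],
            C_p=cs[b][0], C_m=cs[b][1],
            im_pressure_scale=0.5 if b == "RCA" else 1.0,
        )
        for b in BRANCHES
    }


# ---------------------------------------------------------------------------
# Valve coefficient helpers
# ---------------------------------------------------------------------------

M_MV = 0.53  # mitral inertance constant [g/cm^2]
A_MV_REF_DEFAULT = 7.0  # mitral annulus reference area [cm^2]


def _density_inertance(ELCo: float, rho: float) -> float:
    """Aortic-type inertial coefficient 2*pi*rho/sqrt(ELCo), in mmHg s^2/mL."""
    rho_cgs = rho / 1000.0
    return 2.0 * math.pi * rho_cgs / math.sqrt(ELCo) * MMHG_PER_DYN_CM2


def _mitral_inertance(ELCo: float) -> float:
    """Mitral inertial coefficient 2*pi*M_MV/sqrt(ELCo), in mmHg s^2/mL."""
    return 2.0 * math.pi * M_MV / math.sqrt(ELCo) * MMHG_PER_DYN_CM2


# ---------------------------------------------------------------------------
# Full assembly
# ---------------------------------------------------------------------------

_OVERRIDABLE = {
    "C_cor_total_left", "C_cor_total_right", "C_ao", "C_SAC", "R_SA", "R_ub",
    "Q_MPV", "V0_LV", "V0_LA", "A_MV_ref", "E_max_LV", "E_min_LV", "E_max_LA",
    "E_min_LA", "rho", "leak_resistance",
}


def build_model_parameters(
    meas: PatientMeasurements,
    anatomy: CoronaryAnatomy,
    overrides: Optional[dict] = None,
) -> ModelParameters:
    """Populate every circuit element for one patient state.

    Constants and tunable initial values follow the published parameter table;
    the coronary chain is derived from MAP, CO (= forward LVOT SV * HR / 60)
    and the anatomy. Regurgitant and paravalvular-leak paths are instantiated
    only when the corresponding measurement is nonzero. Pure function: the
    inputs are never mutated.
    """
    ov = dict(overrides or {})
    unknown = set(ov) - _OVERRIDABLE
    if unknown:
        raise DomainError(f"unknown override key(s): {sorted(unknown)}")

    rho = float(ov.get("rho", 1050.0))
    T = meas.T

    MAP = compute_map(meas.SBP, meas.DBP, meas.HR)
    CO = meas.forward_LVOT_SV * meas.HR / 60.0  # mL/s
    c_left = float(ov.get("C_cor_total_left", 0.0250))
    c_right = float(ov.get("C_cor_total_right", 0.0125))
    coronary = derive_coronary_branches(MAP, CO, anatomy, c_left, c_right)

    lv = ChamberElastanceParams(
        E_max=float(ov.get("E_max_LV", 2.1)), E_min=float(ov.get("E_min_LV", 0.06)),
        m1=1.32, m2=27.4, tau1=0.269, tau2=0.452,
        V0=float(ov.get("V0_LV", 5.0)), activation_delay=0.0,
    )
    la = ChamberElastanceParams(
        E_max=float(ov.get("E_max_LA", 0.17)), E_min=float(ov.get("E_min_LA", 0.06)),
        m1=1.32, m2=13.1, tau1=0.110, tau2=0.18,
        V0=float(ov.get("V0_LA", 4.0)),
        activation_delay=(1.0 - 0.110) * T,  # atrial kick in late diastole
    )

    elco_av = energy_loss_coefficient(meas.EOA_AV, meas.A_ascending_aorta)
    valve_av = ValveParameters(
        name="aortic", EOA=meas.EOA_AV, ELCo=elco_av,
        inertance_coeff=_density_inertance(elco_av, rho),
    )
    a_mv_ref = float(ov.get("A_MV_ref", A_MV_REF_DEFAULT))
    elco_mv = energy_loss_coefficient(meas.EOA_MV, a_mv_ref)
    valve_mv = ValveParameters(
        name="mitral", EOA=meas.EOA_MV, ELCo=elco_mv,
        inertance_coeff=_mitral_inertance(elco_mv),
    )

    valve_ar = valve_mr = None
    if meas.EOA_AR > 0:
        elco = energy_loss_coefficient(meas.EOA_AR, meas.A_ascending_aorta)
        valve_ar = ValveParameters(
            name="aortic_regurgitant", EOA=meas.EOA_AR, ELCo=elco,
            inertance_coeff=_density_inertance(elco, rho), direction="regurgitant",
        )
    if meas.EOA_MR > 0:
        elco = energy_loss_coefficient(meas.EOA_MR, a_mv_ref)
        valve_mr = ValveParameters(
            name="mitral_regurgitant", EOA=meas.EOA_MR, ELCo=elco,
            inertance_coeff=_density_inertance(elco, rho), direction="regurgitant",
        )

    leak_resistance = None
    if meas.V_leak > 0:
        # initial guess: diastolic gradient ~ (DBP - 10) driving V_leak over diastole
        default_leak = max(meas.DBP - 10.0, 20.0) * (T - meas.T_EJ) / meas.V_leak
        leak_resistance = float(ov.get("leak_resistance", default_leak))

    systemic = SystemicParameters(
        R_SA=float(ov.get("R_SA", 0.8)),
        C_ao=float(ov.get("C_ao", 0.5)),
        C_SAC=float(ov.get("C_SAC", 2.0)),
        # initialised so the upper-body branch carries ~15% of CO at target MAP
        R_ub=float(ov.get("R_ub", (MAP - 4.0) / (0.15 * CO))),
    )
    pulmonary = PulmonaryParameters(Q_MPV=float(ov.get("Q_MPV", CO)))

    return ModelParameters(
        T=T, T_EJ=meas.T_EJ, lv=lv, la=la,
        valve_aortic=valve_av, valve_mitral=valve_mv,
        systemic=systemic, pulmonary=pulmonary, coronary=coronary,
        valve_aortic_regurgitant=valve_ar, valve_mitral_regurgitant=valve_mr,
        leak_resistance=leak_resistance, rho=rho,
        C_cor_total_left=c_left, C_cor_total_right=c_right,
        V_LV_init=max(meas.EDV, 80.0), V_LA_init=60.0,
    )
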