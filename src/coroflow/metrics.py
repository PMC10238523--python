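"""Global and coronary hemodynamic metrics, pre/post deltas, and the
parameter-sensitivity harness.

Conventions: stroke work in joules (1 mmHg·mL = 1.33322e-4 J); flows in mL/s
except totals in mL/min; the systole/diastole boundary is the aortic-valve
opening instant plus the measured ejection time T_EJ.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .circuit import pack_parameters
from .engine import WaveformSet, integrate_to_periodic, simulate_patient
from .errors import DomainError, MetricsError
from .parameters import BRANCHES, compute_map, derive_coronary_branches
from .patients import CoronaryAnatomy, PatientMeasurements

__all__ = [
    "J_PER_MMHG_ML",
    "GlobalHemodynamics",
    "CoronaryHemodynamics",
    "HemodynamicReport",
    "lv_workload",
    "coronary_phase_metrics",
    "report_from_waveforms",
    "compare_pre_post",
    "run_sensitivity",
    "SENSITIVITY_QUANTITIES",
]

J_PER_MMHG_ML = 1.33322e-4


@dataclass
class GlobalHemodynamics:
    LV_workload: float            # J
    max_P_LV: float               # mmHg
    MAP_model: float              # mmHg, time-average aortic-root pressure
    CO: float                     # mL/min
    SBP_model: float              # mmHg
    DBP_model: float              # mmHg
    mean_AV_gradient: float       # mmHg, over ejection
    max_AV_velocity_proxy: float  # m/s, Q_AV,peak / EOA (continuity proxy)
    HR: float                     # beats/min


@dataclass
class BranchPhaseMetrics:
    mean_flow: float           # mL/s, full cycle
    mean_systolic_flow: float
    mean_diastolic_flow: float
    peak_systolic_flow: float
    peak_diastolic_flow: float


@dataclass
class CoronaryHemodynamics:
    branches: dict[str, BranchPhaseMetrics]
    total_coronary_flow: float          # mL/min
    myocardial_blood_flow: Optional[float]  # mL/min/g, None without LV mass
    systole_window: tuple[float, float]     # (t_AV_open, t_AV_open + T_EJ)


@dataclass
class HemodynamicReport:
    label: str
    phase_tag: str
    global_metrics: GlobalHemodynamics
    coronary: CoronaryHemodynamics


def _require_periodic(waves: WaveformSet) -> None:
    if not np.isfinite(waves.convergence_residual) or waves.convergence_residual > 1e-3:
        raise MetricsError(
            "waveforms are not a converged periodic cycle "
            f"(residual {waves.convergence_residual:.3g}); the PV loop is open"
        )


def lv_workload(waves: WaveformSet) -> float:
    """Stroke work: signed shoelace area of the P_LV-V_LV loop, in joules.

    Positive for the physiological counterclockwise traversal in the (V, P)
    plane; traversing the loop in reverse flips the sign."""
    _require_periodic(waves)
    V = waves["V_LV"]
    P = waves["P_LV"]
    Vn = np.roll(V, -1)
    Pn = np.roll(P, -1)
    area_mmhg_ml = 0.5 * float(np.sum(V * Pn - Vn * P))
    return area_mmhg_ml * J_PER_MMHG_ML


def _systole_mask(waves: WaveformSet, T_EJ: float) -> tuple[np.ndarray, float]:
    q_av = waves["Q_AV"]
    peak = float(q_av.max())
    thresh = max(1.0, 0.02 * peak)
    idx = np.flatnonzero(q_av > thresh)
    t_open = float(waves.time[idx[0]]) if idx.size else 0.0
    rel = (waves.time - t_open) % waves.T
    return rel < T_EJ, t_open


def coronary_phase_metrics(
    waves: WaveformSet,
    T_EJ: Optional[float] = None,
    LV_mass: Optional[float] = None,
) -> CoronaryHemodynamics:
    """Per-branch phase-resolved flow metrics.

    Systole is the window [t_AV_open, t_AV_open + T_EJ); diastole is the rest
    of the cycle. Phase means are sample means on the uniform cycle grid, so
    the duration-weighted recombination of the phase means reproduces the
    full-cycle mean exactly."""
    _require_periodic(waves)
    T_EJ = waves.T_EJ if T_EJ is None else T_EJ
    if not (0 < T_EJ < waves.T):
        raise DomainError("require 0 < T_EJ < T")
    sys_mask, t_open = _systole_mask(waves, T_EJ)
    dia_mask = ~sys_mask

    branches = {}
    for b in BRANCHES:
        q = waves[f"q_{b}"]
        branches[b] = BranchPhaseMetrics(
            mean_flow=float(q.mean()),
            mean_systolic_flow=float(q[sys_mask].mean()),
            mean_diastolic_flow=float(q[dia_mask].mean()),
            peak_systolic_flow=float(q[sys_mask].max()),
            peak_diastolic_flow=float(q[dia_mask].max()),
        )
    total = 60.0 * sum(m.mean_flow for m in branches.values())  # mL/min
    mbf = total / LV_mass if LV_mass else None
    return CoronaryHemodynamics(
        branches=branches, total_coronary_flow=total,
        myocardial_blood_flow=mbf, systole_window=(t_open, t_open + T_EJ),
    )


def report_from_waveforms(
    waves: WaveformSet, meas: PatientMeasurements
) -> HemodynamicReport:
    """Assemble the full per-patient metric report from a converged cycle."""
    _require_periodic(waves)
    p_lv = waves["P_LV"]
    p_ao = waves["P_ao_root"]
    q_av = waves["Q_AV"]
    sv = waves.cycle_integral("Q_AV", positive_part=True)
    co_ml_min = sv / waves.T * 60.0

    sys_mask, _ = _systole_mask(waves, waves.T_EJ)
    ej = q_av > max(1.0, 0.02 * float(q_av.max()))
    grad = float(np.mean((p_lv - p_ao)[ej])) if ej.any() else 0.0
    v_max = float(q_av.max()) / meas.EOA_AV / 100.0  # (mL/s)/cm^2 -> m/s

    glob = GlobalHemodynamics(
        LV_workload=lv_workload(waves),
        max_P_LV=float(p_lv.max()),
        MAP_model=float(p_ao.mean()),
        CO=co_ml_min,
        SBP_model=float(p_ao.max()),
        DBP_model=float(p_ao.min()),
        mean_AV_gradient=grad,
        max_AV_velocity_proxy=v_max,
        HR=meas.HR,
    )
    cor = coronary_phase_metrics(waves, waves.T_EJ, meas.LV_mass)
    return HemodynamicReport(
        label=meas.label, phase_tag=meas.phase_tag,
        global_metrics=glob, coronary=cor,
    )


# ---------------------------------------------------------------------------
# Pre/post comparison
# ---------------------------------------------------------------------------

def _pct(pre: float, post: float):
    """Percent change (post - pre)/pre * 100; absolute delta when pre == 0."""
    if pre == 0:
        return {"delta_abs": post - pre}
    return {"delta_pct": (post - pre) / pre * 100.0}


def compare_pre_post(pre: HemodynamicReport, post: HemodynamicReport) -> dict:
    """Percent changes per metric plus the coronary-response classification.

    Classification follows the three observed response patterns: flow
    increased in all three branches, decreased in all three, or mixed."""
    if pre.label != post.label:
        raise DomainError(f"patient labels differ: {pre.label!r} vs {post.label!r}")

    out: dict = {"label": pre.label, "metrics": {}, "branch_flow": {}}
    g_pre, g_post = pre.global_metrics, post.global_metrics
    for name in ("LV_workload", "max_P_LV", "MAP_model", "CO", "SBP_model",
                 "DBP_model", "mean_AV_gradient", "max_AV_velocity_proxy", "HR"):
        out["metrics"][name] = _pct(getattr(g_pre, name), getattr(g_post, name))

    signs = []
    for b in BRANCHES:
        mp = pre.coronary.branches[b].mean_flow
        mq = post.coronary.branches[b].mean_flow
        out["branch_flow"][b] = _pct(mp, mq)
        signs.append(mq - mp)
    if all(s > 0 for s in signs):
        out["classification"] = "all-branches-increase"
    elif all(s < 0 for s in signs):
        out["classification"] = "all-branches-decrease"
    else:
        out["classification"] = "mixed"
    return out


# ---------------------------------------------------------------------------
# Sensitivity harness
# ---------------------------------------------------------------------------

SENSITIVITY_QUANTITIES = (
    "MAP", "CO", "A_LAD", "A_LCX", "A_RCA",
    "C_cor_total_left", "C_cor_total_right",
)


def _perturbed_coronary(meas, anatomy, params, quantity, factor):
    """Re-derive only the coronary elements with one input scaled by factor."""
    MAP = compute_map(meas.SBP, meas.DBP, meas.HR)
    CO = meas.forward_LVOT_SV * meas.HR / 60.0
    c_left, c_right = params.C_cor_total_left, params.C_cor_total_right
    anat = anatomy.model_copy(deep=True)
    if quantity == "MAP":
        MAP *= factor
    elif quantity == "CO":
        CO *= factor
    elif quantity in ("A_LAD", "A_LCX", "A_RCA"):
        b = quantity[2:]
        scale_sten = anat.stenotic_area(b) / anat.area(b)
        object.__setattr__(anat, quantity, anat.area(b) * factor)
        object.__setattr__(anat, f"A_sten_{b}", anat.area(b) * scale_sten)
    elif quantity == "C_cor_total_left":
        c_left *= factor
    elif quantity == "C_cor_total_right":
        c_right *= factor
    else:
        raise DomainError(f"unknown sensitivity quantity {quantity!r}")
    return derive_coronary_branches(MAP, CO, anat, c_left, c_right)


def run_sensitivity(
    meas: PatientMeasurements,
    anatomy: CoronaryAnatomy,
    quantities=SENSITIVITY_QUANTITIES,
    fraction: float = 0.20,
    overrides: Optional[dict] = None,
    baseline=None,
) -> pd.DataFrame:
    """Independent ±``fraction`` variation of the coronary derivation inputs.

    The systemic tuning is frozen at its baseline values so perturbations act
    only through the coronary derivation chain (re-tuning would cancel the
    MAP/CO perturbations by construction of the 4%-of-CO resistance rule).
    Each perturbed model is re-solved to its periodic cycle and the maximum
    over {+, -} of the relative change in mean branch flow is tabulated. A
    branch unaffected by a quantity (e.g. the RCA under a left-compliance
    change is affected only through solver noise) is still reported.

    Returns a frame with one row per quantity: per-branch max relative errors
    (%) and their across-branch mean; a ``failed`` column flags rows whose
    simulation errored. ``baseline`` may carry a precomputed
    ``(waves, result, params)`` triple from :func:`simulate_patient`.
    """
    if baseline is None:
        baseline = simulate_patient(meas, anatomy, overrides)
    base_waves, _, base_params = baseline
    base_flows = np.array([base_waves.cycle_mean(f"q_{b}") for b in BRANCHES])
    base_pack = pack_parameters(base_params)

    rows = []
    for quantity in quantities:
        errs = np.zeros((2, len(BRANCHES)))
        failed = False
        for j, sign in enumerate((+1.0, -1.0)):
            factor = 1.0 + sign * fraction
            pert = copy.deepcopy(base_params)
            pert.coronary = _perturbed_coronary(
                meas, anatomy, base_params, quantity, factor)
            if np.array_equal(pack_parameters(pert), base_pack):
                continue  # identity perturbation: error is exactly zero
            try:
                w = integrate_to_periodic(
                    pert, residual_tol=1e-6, y0=base_waves.y_end, rtol=1e-7,
                )
            except Exception:
                failed = True
                errs[j, :] = np.nan
                continue
            flows = np.array([w.cycle_mean(f"q_{b}") for b in BRANCHES])
            errs[j, :] = np.abs(flows - base_flows) / np.abs(base_flows) * 100.0
        max_err = errs.max(axis=0)
        rows.append({
            "quantity": quantity,
            "fraction": fraction,
            **{f"max_rel_err_{b}_pct": max_err[i] for i, b in enumerate(BRANCHES)},
            "mean_across_branches_pct": float(np.nanmean(max_err)),
            "failed": failed,
        })
    return pd.DataFrame(rows)
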