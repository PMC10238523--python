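"""Patient measurement sets: validation, config I/O and synthetic-cohort generation.

Everything here is bookkeeping — no physiology is computed. The canonical unit
system is mmHg / mL / s / cm²; heart rate is in beats per minute. Configs may
declare convertible units (e.g. kPa for pressures) in a ``units`` block.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import GenerationError, InvariantError, SchemaError

__all__ = [
    "PatientMeasurements",
    "CoronaryAnatomy",
    "FieldDist",
    "CohortSpec",
    "load_patient",
    "save_patient",
    "generate_synthetic_patient",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class PatientMeasurements(BaseModel):
    """Non-invasive measurements for one patient at one time point.

    Pressures come from a brachial cuff; volumes, times and orifice areas from
    Doppler echocardiography. ``T`` and ``T_EJ`` may be omitted: ``T`` is then
    derived as ``60/HR`` and ``T_EJ`` as ``0.3*sqrt(T)`` (classic systolic
    ejection-time scaling).
    """

    model_config = ConfigDict(validate_assignment=True)

    label: str = "patient"
    phase_tag: Literal["pre", "post"] = "pre"
    SBP: float = Field(description="brachial systolic pressure [mmHg]")
    DBP: float = Field(description="brachial diastolic pressure [mmHg]")
    HR: float = Field(description="heart rate [beats/min]")
    T: Optional[float] = Field(default=None, description="cardiac cycle duration [s]")
    T_EJ: Optional[float] = Field(default=None, description="systolic ejection time [s]")
    forward_LVOT_SV: float = Field(description="forward LVOT stroke volume [mL]")
    EOA_AV: float = Field(description="aortic valve effective orifice area [cm^2]")
    EOA_MV: float = Field(description="mitral valve effective orifice area [cm^2]")
    A_LVOT: float = Field(description="LVOT cross-sectional area [cm^2]")
    A_ascending_aorta: float = Field(description="ascending aorta cross-sectional area [cm^2]")
    EOA_AR: float = Field(default=0.0, description="aortic regurgitant orifice area [cm^2]")
    EOA_MR: float = Field(default=0.0, description="mitral regurgitant orifice area [cm^2]")
    V_leak: float = Field(default=0.0, description="paravalvular leak volume [mL/cycle]")
    EDV: float = Field(description="end-diastolic volume [mL]")
    ESV: float = Field(description="end-systolic volume [mL]")
    LV_mass: Optional[float] = Field(default=None, description="LV mass [g] (for MBF only)")

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientMeasurements":
        def fail(rule: str):
            raise InvariantError(f"{self.label}: invariant violated: {rule}")

        if not (self.SBP > self.DBP > 0):
            fail("SBP > DBP > 0")
        if self.HR <= 0:
            fail("HR > 0")
        if self.T is None:
            object.__setattr__(self, "T", 60.0 / self.HR)
        elif abs(self.T - 60.0 / self.HR) > 0.01 * self.T:
            fail("T = 60/HR within 1%")
        if self.T_EJ is None:
            object.__setattr__(self, "T_EJ", 0.3 * math.sqrt(self.T))
        if not (0 < self.T_EJ < self.T):
            fail("0 < T_EJ < T")
        if not (0 < self.ESV < self.EDV):
            fail("0 < ESV < EDV")
        for name in ("EOA_AV", "EOA_MV", "A_LVOT", "A_ascending_aorta"):
            if getattr(self, name) <= 0:
                fail(f"{name} > 0")
        for name in ("EOA_AR", "EOA_MR", "V_leak"):
            if getattr(self, name) < 0:
                fail(f"{name} >= 0")
        if not (self.EOA_AV < self.A_ascending_aorta):
            fail("EOA_AV < A_ascending_aorta")
        if self.forward_LVOT_SV <= 0:
            fail("forward_LVOT_SV > 0")
        if self.LV_mass is not None and self.LV_mass <= 0:
            fail("LV_mass > 0")
        return self


class CoronaryAnatomy(BaseModel):
    """CT-derived proximal cross-sectional areas of the three coronary branches.

    Stenotic areas default to the branch area (no stenosis)."""

    model_config = ConfigDict(validate_assignment=True)

    A_LAD: float
    A_LCX: float
    A_RCA: float
    A_sten_LAD: Optional[float] = None
    A_sten_LCX: Optional[float] = None
    A_sten_RCA: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "CoronaryAnatomy":
        for b in ("LAD", "LCX", "RCA"):
            area = getattr(self, f"A_{b}")
            if area <= 0:
                raise InvariantError(f"A_{b} must be > 0")
            sten = getattr(self, f"A_sten_{b}")
            if sten is None:
                object.__setattr__(self, f"A_sten_{b}", area)
            elif not (0 < sten <= area):
                raise InvariantError(f"0 < A_sten_{b} <= A_{b}")
        return self

    def area(self, branch: str) -> float:
        return getattr(self, f"A_{branch}")

    def stenotic_area(self, branch: str) -> float:
        return getattr(self, f"A_sten_{branch}")


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_MEAS_OPTIONAL = {"T", "T_EJ", "LV_mass", "EOA_AR", "EOA_MR", "V_leak"}
_MEAS_FIELDS = (set(PatientMeasurements.model_fields)
                - {"label", "phase_tag"} - _MEAS_OPTIONAL)
_ANAT_FIELDS = {"A_LAD", "A_LCX", "A_RCA"}
_ANAT_OPTIONAL = {"A_sten_LAD", "A_sten_LCX", "A_sten_RCA"}

#: canonical unit per field kind, and accepted convertible units (factor to canonical)
_CANONICAL_UNITS = {
    "pressure": ("mmHg", {"kPa": 7.50062}),
    "area": ("cm^2", {"cm2": 1.0, "mm^2": 0.01, "mm2": 0.01}),
    "volume": ("mL", {"ml": 1.0, "L": 1000.0}),
    "time": ("s", {"ms": 0.001}),
    "rate": ("beats/min", {"bpm": 1.0, "1/min": 1.0}),
    "mass": ("g", {"kg": 1000.0}),
}

_FIELD_KIND = {
    "SBP": "pressure", "DBP": "pressure",
    "HR": "rate", "T": "time", "T_EJ": "time",
    "forward_LVOT_SV": "volume", "V_leak": "volume", "EDV": "volume", "ESV": "volume",
    "EOA_AV": "area", "EOA_MV": "area", "A_LVOT": "area", "A_ascending_aorta": "area",
    "EOA_AR": "area", "EOA_MR": "area",
    "A_LAD": "area", "A_LCX": "area", "A_RCA": "area",
    "A_sten_LAD": "area", "A_sten_LCX": "area", "A_sten_RCA": "area",
    "LV_mass": "mass",
}


def _convert(field: str, value: float, unit: Optional[str]) -> float:
    kind = _FIELD_KIND[field]
    canonical, convertible = _CANONICAL_UNITS[kind]
    if unit is None or unit == canonical:
        return value
    if unit in convertible:
        return value * convertible[unit]
    raise SchemaError(
        f"field {field!r}: unit {unit!r} is neither the canonical {canonical!r} "
        f"nor one of the convertible units {sorted(convertible)}"
    )


def load_patient(config_path) -> tuple[PatientMeasurements, CoronaryAnatomy]:
    """Read and validate a patient config (YAML or JSON).

    The config is a flat mapping whose keys match the measurement and anatomy
    field names, plus optional ``label``, ``phase_tag`` and a ``units`` block
    mapping field names to declared units.
    """
    path = Path(config_path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return parse_patient_dict(raw, default_label=path.stem)


def parse_patient_dict(raw: dict, default_label: str = "patient") -> tuple[PatientMeasurements, CoronaryAnatomy]:
    raw = dict(raw)
    units = raw.pop("units", {}) or {}
    if not isinstance(units, dict):
        raise SchemaError("'units' block must be a mapping of field name to unit")
    for key in units:
        if key not in _FIELD_KIND:
            raise SchemaError(f"'units' block names unknown field {key!r}")

    meas_kwargs = {"label": raw.pop("label", default_label)}
    if "phase_tag" in raw:
        meas_kwargs["phase_tag"] = raw.pop("phase_tag")
    anat_kwargs = {}

    known = _MEAS_FIELDS | _MEAS_OPTIONAL | _ANAT_FIELDS | _ANAT_OPTIONAL
    for key, value in raw.items():
        if key not in known:
            raise SchemaError(f"unknown field {key!r} in patient config")
        value = _convert(key, float(value), units.get(key))
        if key in _ANAT_FIELDS or key in _ANAT_OPTIONAL:
            anat_kwargs[key] = value
        else:
            meas_kwargs[key] = value

    for req, kwargs, cls in ((_MEAS_FIELDS, meas_kwargs, "measurement"),
                             (_ANAT_FIELDS, anat_kwargs, "anatomy")):
        missing = sorted(req - set(kwargs))
        if missing:
            raise SchemaError(f"missing required {cls} field(s): {', '.join(missing)}")

    meas = PatientMeasurements(**meas_kwargs)
    anatomy = CoronaryAnatomy(**anat_kwargs)
    return meas, anatomy


def save_patient(meas: PatientMeasurements, anatomy: CoronaryAnatomy, path) -> None:
    """Write a patient config (YAML) that :func:`load_patient` round-trips."""
    doc = {k: v for k, v in meas.model_dump().items() if v is not None}
    doc.update(anatomy.model_dump())
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

class FieldDist(BaseModel):
    """Mean/SD of one generated field, truncated to [lo, hi]."""

    mean: float
    sd: float = 0.0
    lo: float = -math.inf
    hi: float = math.inf

    @model_validator(mode="after")
    def _check(self) -> "FieldDist":
        if self.sd < 0:
            raise GenerationError("sd must be >= 0")
        if not (self.lo <= self.mean <= self.hi):
            raise GenerationError(
                f"infeasible truncation: mean {self.mean} outside [{self.lo}, {self.hi}]"
            )
        return self


def _d(mean, sd, lo, hi) -> FieldDist:
    return FieldDist(mean=mean, sd=sd, lo=lo, hi=hi)


#: Pre-intervention cohort defaults. Printed cohort values (severe aortic
#: stenosis, n=19): HR 71±14 bpm, SBP 133.0±18.9, DBP 70.5±9.2 mmHg,
#: EF 59.9±8.4 %, stenotic EOA 0.84±0.19 cm². The remaining fields are not
#: printed for the cohort; defaults are typical adult values, documented in
#: docs/methods.md and overridable per field.
DEFAULT_PRE: dict[str, FieldDist] = {
    "HR": _d(71.0, 14.0, 45.0, 110.0),
    "SBP": _d(133.0, 18.9, 95.0, 195.0),
    "DBP": _d(70.5, 9.2, 45.0, 100.0),
    "EF": _d(0.599, 0.084, 0.35, 0.78),
    "EDV": _d(120.0, 25.0, 75.0, 210.0),
    "EOA_AV": _d(0.84, 0.19, 0.45, 1.5),
    "EOA_MV": _d(2.5, 0.4, 1.6, 4.0),
    "A_LVOT": _d(3.5, 0.5, 2.2, 5.5),
    "A_ascending_aorta": _d(8.0, 1.2, 5.0, 12.0),
    "T_EJ_offset": _d(0.0, 0.02, -0.06, 0.06),
    "LV_mass": _d(110.0, 25.0, 60.0, 220.0),
    "EOA_AR": _d(0.0, 0.0, 0.0, 1.0),
    "EOA_MR": _d(0.0, 0.0, 0.0, 1.0),
    "V_leak": _d(0.0, 0.0, 0.0, 40.0),
}

#: Post-intervention defaults (90-day follow-up column): HR 73±13,
#: SBP 142.0±22.3, DBP 72.0±15.4, EF 62.3±7.0. The post EOA of the implanted
#: valve is not drawn directly; it is derived from a drawn target peak
#: transvalvular velocity (printed post mean 2.75±0.65 m/s) via continuity.
DEFAULT_POST: dict[str, FieldDist] = {
    **{k: v for k, v in DEFAULT_PRE.items()},
    "HR": _d(73.0, 13.0, 45.0, 110.0),
    "SBP": _d(142.0, 22.3, 95.0, 200.0),
    "DBP": _d(72.0, 15.4, 45.0, 105.0),
    "EF": _d(0.623, 0.070, 0.35, 0.80),
}

#: Proximal coronary calibers (mm): not printed for the cohort; typical adult
#: values, SD 0.4 mm.
DEFAULT_CORONARY_DIAMETERS: dict[str, FieldDist] = {
    "d_LAD": _d(3.7, 0.4, 2.2, 5.5),
    "d_LCX": _d(3.4, 0.4, 2.2, 5.5),
    "d_RCA": _d(3.9, 0.4, 2.2, 5.5),
}

DEFAULT_POST_PEAK_VELOCITY = _d(2.75, 0.65, 1.6, 4.2)  # m/s


class CohortSpec(BaseModel):
    """Distributional description of a synthetic pre/post intervention cohort."""

    n_patients: int = 19
    seed: int = 0
    paired: bool = True
    pre: dict[str, FieldDist] = Field(default_factory=lambda: dict(DEFAULT_PRE))
    post: dict[str, FieldDist] = Field(default_factory=lambda: dict(DEFAULT_POST))
    coronary: dict[str, FieldDist] = Field(
        default_factory=lambda: dict(DEFAULT_CORONARY_DIAMETERS)
    )
    post_peak_velocity: FieldDist = Field(default_factory=lambda: DEFAULT_POST_PEAK_VELOCITY)

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_patients < 1:
            raise GenerationError("n_patients must be >= 1")
        for block, defaults in (("pre", DEFAULT_PRE), ("post", DEFAULT_POST),
                                ("coronary", DEFAULT_CORONARY_DIAMETERS)):
            spec = dict(defaults)
            spec.update(getattr(self, block))
            unknown = set(getattr(self, block)) - set(defaults)
            if unknown:
                raise GenerationError(f"unknown field(s) in {block!r}: {sorted(unknown)}")
            object.__setattr__(self, block, spec)
        return self


_PRE_DRAW_ORDER = ("HR", "DBP", "SBP", "EF", "EDV", "EOA_AV", "EOA_MV", "A_LVOT",
                   "A_ascending_aorta", "T_EJ_offset", "LV_mass", "EOA_AR", "EOA_MR",
                   "V_leak")


def _truncated(rng: np.random.Generator, dist: FieldDist, z: float | None = None) -> tuple[float, float]:
    """Draw one value; returns (value, z-score used). z may be imposed for pairing."""
    if z is None:
        z = float(rng.standard_normal())
    if dist.sd == 0.0:
        return dist.mean, z
    return float(np.clip(dist.mean + dist.sd * z, dist.lo, dist.hi)), z


def _assemble(label: str, phase: str, draws: dict[str, float]) -> PatientMeasurements:
    HR = draws["HR"]
    T = 60.0 / HR
    DBP = draws["DBP"]
    SBP = max(draws["SBP"], DBP + 20.0)  # cuff pressures must keep a plausible pulse
    EDV = draws["EDV"]
    EF = draws["EF"]
    ESV = EDV * (1.0 - EF)
    sv = EDV * EF
    t_ej = float(np.clip(0.3 * math.sqrt(T) + draws["T_EJ_offset"], 0.15, 0.6 * T))
    return PatientMeasurements(
        label=label, phase_tag=phase, SBP=SBP, DBP=DBP, HR=HR, T=T, T_EJ=t_ej,
        forward_LVOT_SV=sv, EOA_AV=draws["EOA_AV"], EOA_MV=draws["EOA_MV"],
        A_LVOT=draws["A_LVOT"], A_ascending_aorta=draws["A_ascending_aorta"],
        EOA_AR=draws["EOA_AR"], EOA_MR=draws["EOA_MR"], V_leak=draws["V_leak"],
        EDV=EDV, ESV=ESV, LV_mass=draws["LV_mass"],
    )


def generate_synthetic_patient(
    spec: CohortSpec, index: int
) -> tuple[PatientMeasurements, PatientMeasurements, CoronaryAnatomy]:
    """Draw one paired pre/post patient, reproducible from ``(spec.seed, index)``.

    Each field is drawn from a clipped normal with the spec's mean/SD. The
    pre and post states of a patient share the per-field z-scores (perfect
    rank pairing) and the same coronary anatomy. The post aortic-valve EOA is
    derived from a drawn target peak velocity so that the modelled peak valve
    velocity lands near the printed post-intervention mean.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index)]))
    label = f"P{index:02d}"

    zs: dict[str, float] = {}
    pre_draws: dict[str, float] = {}
    for name in _PRE_DRAW_ORDER:
        pre_draws[name], zs[name] = _truncated(rng, spec.pre[name])
    pre = _assemble(label, "pre", pre_draws)

    post_draws = {name: _truncated(rng, spec.post[name], zs[name])[0] for name in _PRE_DRAW_ORDER}
    post = _assemble(label, "post", post_draws)
    # Post EOA via continuity: peak AV flow of a half-sine ejection is
    # (pi/2) * SV / T_EJ [mL/s]; peak velocity v [m/s] = Q_peak / (100 * EOA).
    v_target, _ = _truncated(rng, spec.post_peak_velocity)
    q_peak = 0.5 * math.pi * post.forward_LVOT_SV / post.T_EJ
    eoa_post = float(np.clip(q_peak / (100.0 * v_target), 0.9, 0.9 * post.A_ascending_aorta))
    post = post.model_copy(update={"EOA_AV": eoa_post})

    diams = {name: _truncated(rng, dist)[0] for name, dist in spec.coronary.items()}
    areas = {f"A_{b}": math.pi * (diams[f'd_{b}'] / 10.0) ** 2 / 4.0 for b in ("LAD", "LCX", "RCA")}
    anatomy = CoronaryAnatomy(**areas)
    return pre, post, anatomy


def generate_cohort(spec: CohortSpec):
    """Yield ``(pre, post, anatomy)`` for every patient index in the spec."""
    return [generate_synthetic_patient(spec, i) for i in range(spec.n_patients)]
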