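# Methods

## Scope and intent

`coroflow` reconstructs a patient-specific closed-loop circulation — left
atrium, left ventricle, aortic and mitral valves, systemic and pulmonary
beds, and the three main coronary branches — from measurements that can all
be collected without catheters: a brachial cuff (SBP, DBP), Doppler
echocardiography (heart rate, cycle and ejection times, forward LVOT stroke
volume, valve effective orifice areas, EDV/ESV, regurgitant orifice areas,
paravalvular leak volume) and CT (proximal coronary cross-sectional areas,
optional stenotic areas). The model's outputs are one converged cardiac
cycle of every pressure/flow of interest plus scalar metrics: LV stroke
work, peak LV pressure, model MAP, cardiac output, mean transvalvular
gradient, and phase-resolved coronary branch flows.

## Circuit model

### Chambers

LV and LA are time-varying elastance elements `P = E(t)(V − V0)` with the
double-Hill activation

    E(t) = (E_max − E_min) · [g1/(1+g1)] · [1/(1+g2)] / N + E_min,
    g1 = (t/τ1)^m1,  g2 = (t/τ2)^m2,

where `N` is the cycle maximum of the bracketed product, computed
numerically (4096-point grid plus bounded local refinement) so that
`max_t E(t) = E_max` holds to ~1e-10. Parameters (mmHg/mL, fractions of T):

| chamber | E_max | E_min | m1 | m2 | τ1 | τ2 | V0 (mL) |
|---|---|---|---|---|---|---|---|
| LV | 2.1 | 0.06 | 1.32 | 27.4 | 0.269 T | 0.452 T | 5 |
| LA | 0.17 | 0.06 | 1.32 | 13.1 | 0.110 T | 0.18 T | 4 |

The atrial activation is phase-shifted so its onset falls at `T − τ1·T`
(atrial kick in late diastole, completing around the ventricular activation
onset). The unstressed volumes are not measured quantities; the defaults
give physiological chamber pressures at cohort-mean EDV/ESV and are exposed
as overrides (`V0_LV`, `V0_LA`).

### Valves

Forward valve paths carry an inductive state Q with

    ΔP = B·dQ/dt + K·Q|Q|,   K = ρ_cgs / (2·ELCo²) / 1333.22  [mmHg/(mL/s)²]

and `ELCo = EOA·A/(A − EOA)`. The aortic valve uses the density-based
inertial coefficient `B = 2πρ_cgs/√ELCo / 1333.22` (ρ = 1050 kg/m³,
ρ_cgs = 1.05 g/cm³) with the ascending-aorta area as reference `A`; the
mitral valve uses the inertance constant M_MV = 0.53 g/cm² in the same form,
`B = 2π·M_MV/√ELCo / 1333.22`, with a configurable mitral annulus reference
area (default 7.0 cm², override `A_MV_ref`). Aortic/mitral regurgitant
paths, present only when the corresponding regurgitant orifice area is
nonzero, are reverse-oriented valves with the same law. The paravalvular
leak is a constant-resistance path in parallel with the aortic valve whose
resistance is tuned so the per-cycle retrograde volume matches the measured
`V_leak`.

Valve opening/closing is a smooth diode: the closed-path resistance
(1000 mmHg·s/mL) is blended in over a 0.1 mmHg gradient window via a tanh
switch. Hard switches break variable-step stiff integration; the price is a
sub-0.1 mL/s reverse trickle through a closed valve, negligible against a
~70 mL stroke volume and asserted small in the tests.

### Coronary branches

Each branch is the classic three-resistor / two-capacitor coronary
boundary circuit with an intramyocardial pressure source P_im:
`q_in = (P_in − P_p)/R_p`, `q_m = (P_p − P_m)/R_m`,
`q_out = (P_m − P_out)/R_d`, with `C_p` to ground at the proximal node and
`C_m` referencing the medial node to P_im, so the states are `P_p` and
`U_m = P_m − P_im`:

    C_p·dP_p/dt = q_in − q_m,      C_m·dU_m/dt = q_m − q_out.

P_im is `P_LV` for LAD/LCX and `0.5·P_LV` for the RCA (no right ventricle is
modelled). The medial capacitor could alternatively be referenced to ground
with the source term carried explicitly; referencing it to the source is the
reading consistent with a two-state branch and is what makes ventricular
compression throttle systolic inflow — the mechanism behind diastolic-
dominant coronary perfusion. Inlets attach at the aortic-root node, outlets
drain to the constant venous pressure P_CV0 = 4 mmHg.

Element values derive from the measurements:

1. `MAP = DBP + [1/3 + 0.0012·HR]·(SBP − DBP)` (cuff formula);
2. `R_total = MAP/(0.04·CO)` with `CO = forward_LVOT_SV·HR/60` in mL/s —
   the coronary bed is assumed to carry 4.0% of cardiac output. The forward
   LVOT stroke volume (not EDV−ESV) is used because it is the quantity the
   tuning reproduces and the echo-measurable systemic output;
3. branch totals by the Murray-type allocation
   `R_j = (Σ_i √A_i^2.6 / √A_j^2.6)·R_total` pooled over all three branches
   (their parallel combination returns `R_total` exactly — an identity the
   tests assert to 1e-12);
4. stenosis correction `R_red = R·α⁻²`, `α = A_sten/A ∈ (0, 1]`;
5. resistor split 0.32/0.52/0.16 (proximal/medial/distal);
6. compliance per side shared by area (left total across LAD+LCX; RCA takes
   the right total), then split 0.11/0.89 (proximal/medial).

The side compliance totals are not identifiable from the non-invasive
inputs; defaults `C_left = 0.0250`, `C_right = 0.0125` mL/mmHg give
physiological biphasic waveforms and are exposed as overrides. Mean branch
flow is provably insensitive to them in the periodic state (capacitors carry
zero mean current), which the sensitivity harness confirms; they shape the
waveform and its peaks only.

### Systemic and pulmonary circulation

Aortic root node (C_ao, with coronaries and an upper-body branch R_ub to
P_CV0) → R_ao + R_pda in series → systemic bed node (C_SAC) → R_SA + R_SV →
P_CV0. Constants: R_ao = R_SV = R_pda = 0.05 mmHg·s/mL, P_CV0 = 4 mmHg.
C_ao (0.5), C_SAC (2), R_SA (0.8) are tuning initial values; R_ub is
initialised to direct 15% of CO at target MAP.

The right heart is not modelled: the pulmonary valve inflow is an imposed
half-sine of duration T_EJ per cycle scaled so its cycle mean equals the
tunable Q_MPV. The pulmonary chain PA node (C_PA = 4) → R_PA + R_PC with
inertance L_PC → venous node (C_PVC = 40) → R_PVC + R_PV with inertance
L_PV → LA uses the published constants (R_PV 0.002, R_PVC 0.001, R_PC 0.21,
R_PA 0.01 mmHg·s/mL; L_PV 5e-4, L_PC 3e-4 mmHg·s²/mL). Both pulmonary
inductor currents are kept as states so these inertances actually enter the
dynamics; the state vector is therefore 18-dimensional (2 volumes, 6
capacitor pressures, 4 valve flows, 2 pulmonary inductor flows — regurgitant
slots held at zero when those paths are absent — and 2 per coronary branch).

## Numerics

- **Integration.** LSODA (via `scipy.integrate.odeint`) with initial step
  1e-4 s, rtol 1e-7–1e-9 depending on context, cycle by cycle on a uniform
  301-point grid. Initial state: all capacitor pressures and inductor flows
  zero; chamber volumes at EDV-scale guesses (an elastance chamber started
  exactly at V0 is degenerate). The derivative is JIT-compiled with numba
  (plain-Python fallback if numba is absent).
- **Periodicity.** Convergence residual = relative Frobenius norm of the
  difference between consecutive cycles' state trajectories on the output
  grid; the reported-waveform threshold is 1e-6. From a cold start the
  cohort-mean patient needs ~90 cycles (the venous compliance C_PVC = 40 is
  the slow mode, contraction ≈ 0.88/cycle); warm restarts converge in 1–3.
  The solver-noise floor of the cycle map sits near 1e-8 at rtol 1e-9.
- **Tuning.** A deterministic damped fixed-point loop with physics-informed
  multiplicative updates: Q_MPV scales with the stroke-volume ratio; R_SA
  with the mean-pressure error; C_ao and C_SAC scale *together* with the
  pulse-pressure ratio (pulse pressure and the diastolic decay constant
  R·C_total both depend on the total compliance — adjusting C_ao alone
  saturates); R_ub with the upper-body flow-share ratio; the leak resistance
  with the leak-volume ratio (damped secant rather than bisection — same
  0.5 mL tolerance, fewer solves). Objective evaluations run at a relaxed
  cycle residual (1e-4) with warm starts; the final cycle is re-solved at
  1e-6 and re-verified against the tolerances (SBP/DBP ±1 mmHg, SV ±1 mL,
  upper-body share ±0.5 pp). A derivative-free least-squares polish over
  (log R_SA, log C_ao, log C_SAC) is a fallback if the fixed point stalls;
  in practice the loop converges in 4–10 iterations (~1–3 s per patient).
  The procedure is a pure function of its inputs and is idempotent within
  the tolerances.
- **Degenerate inputs.** Formula domains are guarded (`DomainError`):
  EOA ≥ A (ELCo diverges), α outside (0, 1], non-positive pressures/flows.
  Non-finite states abort integration with a diagnostic naming the circuit
  component.

## Metrics

- **LV stroke work**: signed shoelace area of the P–V loop × 1.33322e-4 J
  per mmHg·mL; positive for the physiological counterclockwise traversal.
  Requested on non-periodic waveforms it raises (open loop).
- **Phase split**: systole is `[t_AV_open, t_AV_open + T_EJ)` using the
  measured ejection time rather than pressure-crossing detection (T_EJ is a
  declared input); diastole is the remainder. Phase means are sample means
  on the uniform grid so their duration-weighted recombination equals the
  full-cycle mean exactly.
- **Max AV velocity** is reported as the continuity proxy
  `Q_AV,peak/EOA_AV` (m/s) — a proxy because clinical values are measured by
  Doppler, not derived from a flow waveform.
- **Pre/post deltas**: percent change per metric (absolute delta when the
  baseline is zero) and the three-way coronary response classification
  (all-increase / all-decrease / mixed).
- **Sensitivity harness**: each coronary derivation input (MAP, CO, the
  three branch areas, the two side compliance totals) is varied ±20%
  independently; only the coronary elements are re-derived and the systemic
  tuning stays frozen at baseline — the only reading under which MAP/CO
  perturbations can move coronary flow at all, since re-tuning would restore
  the 4%-of-CO construction by definition. Identity perturbations are
  recognised by parameter-vector equality and reported as exactly zero.

## Synthetic cohort generator

The generator defines the study conditions. Each field is drawn from a
clipped normal; printed cohort statistics anchor HR, SBP, DBP, EF and the
stenotic EOA in the pre state and HR/SBP/DBP/EF in the post state. Pre and
post share per-field z-scores (perfect rank pairing) and coronary anatomy.
The post aortic EOA is not drawn directly: a target peak transvalvular
velocity is drawn from the printed post distribution (2.75 ± 0.65 m/s) and
converted through continuity with the patient's half-sine ejection peak
flow, so the modelled post velocities land on the reported scale.

Values the cohort table does not print are package choices, documented here
and overridable per field: EDV 120 ± 25 mL (ESV from the drawn EF; forward
SV = EF·EDV, consistent with the printed EOA and peak-velocity scale),
mitral EOA 2.5 ± 0.4 cm², LVOT area 3.5 ± 0.5 cm², ascending aorta
8.0 ± 1.2 cm², LV mass 110 ± 25 g, proximal coronary diameters 3.7/3.4/3.9
± 0.4 mm (LAD/LCX/RCA — typical adult calibers), ejection time
0.3·√T ± 0.02 s, and zero regurgitation/leak by default. All randomness
flows through one `numpy` generator seeded by `(seed, index)`; generation is
bit-reproducible and with all SDs zero the generator is the identity on the
means.

What the generator does *not* emulate: measurement error and intra-observer
variability, joint correlations beyond the rank pairing (e.g. EOA–EF
coupling), comorbidities (coronary stenoses default to absent), and any
per-patient relationship between anatomy and hemodynamics. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's correctness and the
model's qualitative physiology, not clinical accuracy on real patients.

## Problem sizes used in tests and the acceptance script

Cohort-level checks run on seeded synthetic cohorts: 19 patients for tuning
recovery, 5 patients for the sensitivity summaries; waveforms use a
301-point cycle grid. These sizes give stable cohort statistics while
keeping a full run in the minutes range on one CPU.

## Known limitations

- No coronary autoregulation: branch resistance is fixed per state, so MAP
  changes translate directly into flow changes instead of being buffered.
- No right ventricle; the RCA's intramyocardial source is a fixed 0.5·P_LV
  and pulmonary inflow is imposed rather than generated.
- Cuff pressures are compared against aortic-root extrema (no
  brachial-to-central transfer function).
- The 4%-of-CO assumption fixes mean total coronary flow by construction;
  the model distributes and shapes it but cannot discover a different total.
- Elastance parameters are population constants; only the loading and
  timing, not intrinsic contractility, are personalised.
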