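# gaitcost

Joint-space modeling of the metabolic cost of walking: instantaneous
metabolic energy expenditure (MEE) rate, instantaneous cost of transport
(ICOT), and phase-specific cost of transport (COT), with subject-specific
heat coefficients estimated from walking metabolic data by constrained
nonlinear least squares.

The package is for biomechanists and movement scientists who have joint
kinematics and inverse-dynamics torques (from standard gait analysis) and
want a subject-specific, time-resolved estimate of metabolic rate — a
quantity that indirect calorimetry can only deliver as a steady-state
average.

## The model

The whole body is treated as a closed thermodynamic system whose internal
work and heat are written in joint space over the `n` generalized
coordinates (joint angles) `q_i` with velocities `q̇_i` and actuator
torques `τ_i`:

```
Ė_met(t) = Σ_i τ_i q̇_i  +  Σ_i h_am,i |τ_i|  +  Σ_i h_sl,i |τ_i q̇_i|  +  Σ_i Q̇_cc,i(t)  +  Ė_bmr
```

where the first term is net joint power; `h_am,i |τ_i|` is the
activation–maintenance heat rate (coefficient in 1/s); `h_sl,i |τ_i q̇_i|`
is the shortening–lengthening heat rate (dimensionless coefficient);
`Q̇_cc,i ≥ 0` is optional torque-independent cocontraction heat (zero by
default); and `Ė_bmr` is the measured sitting basal metabolic rate. The
second law requires every heat term to be non-negative.

Each coefficient is the product of a subject factor and a DOF factor,
built from normalized subject parameters (mass `m_n = M/100`, age
`a_n = A/100`, height `h_n = H/10`) and the strength-scaled normalized
reference torque of the DOF:

```
h_i = (w0 + w1 m_n + w2 a_n + w3 h_n) · (1 + w4 (τ_knee^max/τ̃_knee^max) τ̃_i^max/100)
```

The ten weights `w` (five per heat component) are estimated by minimizing
`(1/2N) Σ_k (Ē_met,k − ⟨Ė_met⟩_k)²` over `N` measured strides, subject to
non-negativity of both factors, per-DOF non-negativity of work-plus-heat
at every sample (metabolic energy cannot be recharged by negative work),
and an upper bound from the subject's aerobic capacity. A packaged fixture
carries a published estimate of `w`.

Derived quantities: `ICOT(t) = Ė_met/(M g v)`, interval
`COT = ⟨Ė_met⟩_T / (M g ⟨v⟩_T)` for any interval `T` (whole strides,
single-support or double-support phases), the Laurent COT-vs-speed curve
`c₋₁/v + c₀ + c₁ v`, and the Froude number `v/√(g·0.53H)`.

A first-class synthetic-data generator emulates the study design this
model targets (sex-specific cohorts, five speeds at 70–130% of preferred,
double-support fraction falling from 34.9% to 22.1% with speed, push-off
torque bursts in double support, calorimetry-style measurements), so the
whole pipeline can be exercised and the estimator validated by parameter
recovery without any recorded data.

## Worked example

```python
import numpy as np
import gaitcost as gc

subject = gc.SubjectProfile(id="demo", sex="M", mass_kg=87.9, height_m=1.83,
                            age_yr=31, knee_max_torque_Nm=212.4, bmr_W=85.0)
catalog = gc.default_catalog("M")
h = gc.heat_coefficients(gc.published_weights(), subject, catalog)

rng = np.random.default_rng(42)
trial = gc.generate_gait_trial(subject, 100.0, gc.GeneratorConfig(seed=42),
                               rng, catalog=catalog)
trace = gc.mee_rate(trial, h, subject.bmr_W)
print(round(float(np.trapezoid(trace.e_met, trace.t) / trial.duration_s), 1))
```

prints `386.8` — the stride-average MEE in watts for this synthetic
stride at 1.29 m/s (4.4 W/kg, a typical walking rate), of which ~22% is
BMR and most of the rest shortening–lengthening heat. The scripts in
`examples/` walk through each capability (instantaneous traces, phase
COT, weight estimation, the COT–speed curve, calorimetry processing) and
print the numbers with one-line interpretations; `gaitcost --help`
exposes the same pipeline as shell subcommands (`simulate`, `evaluate`,
`estimate`, `validate`, `cot-curve`).

A hand check of the rate model itself: one DOF with `τ = 10 N·m`,
`q̇ = 1 rad/s`, `h_am = 0.02/s`, `h_sl = 0.1`, BMR 80 W gives
`10 + 0.2 + 1 + 80 = 91.2 W`.

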