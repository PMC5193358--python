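# Methods

## Model

The metabolic energy expenditure (MEE) rate is modeled in joint space.
Writing the first law for the body as a closed system and splitting
internal work and heat by muscle group, everything not attributable to
voluntary skeletal-muscle actuation (smooth/cardiac muscle work and heat,
basal torque-dependent cocontraction, tissue-level metabolism) is folded
into a single measured parameter, the sitting basal metabolic rate
`Ė_bmr`. What remains is net joint power plus two skeletal-muscle heat
terms mapped from muscle energetics to joint space:

* activation–maintenance heat `h_am,i |τ_i|` — proportional to torque
  magnitude; `h_am` carries units 1/s (forced dimensionally: watts per
  newton-meter);
* shortening–lengthening heat `h_sl,i |τ_i q̇_i|` — proportional to the
  magnitude of joint power; `h_sl` dimensionless.

Absolute values implement the second law: eccentric and concentric
episodes with equal |power| dissipate equally, and no heat term is ever
negative. Torque-independent cocontraction heat `Q̇_cc ≥ 0` is accepted
as an input trace for completeness but defaults to zero (subjects walking
naturally are assumed not to stiffen voluntarily) and is excluded from
estimation.

The coefficients are constants per DOF and subject, built by separation
of variables as (subject factor) × (DOF factor); the subject factor is
linear in normalized mass, age and height, the DOF factor affine in the
strength-scaled normalized reference torque. Age enters as an accessible
surrogate for aerobic capacity. The model deliberately does not resolve
angle/velocity dependence of the coefficients; a hook for state-dependent
coefficients exists in the interface but the estimable form is the
separable constant one.

### Normalization and strength scaling

Subject parameters are divided by their maximum order of magnitude (100
for mass in kg, age in years, and torques in N·m; 10 for height in m) so
the ten regression weights are comparably scaled. The knee strength ratio
`τ_knee^max/τ̃_knee^max` is dimensionless and used raw. A subject's
maximum torque at DOF i is the measured maximum isometric knee extension
torque linearly scaled by the catalog ratio `τ̃_i^max/τ̃_knee^max`;
mirrored left/right DOFs share reference values, so coefficients are
left–right symmetric by construction.

The default 42-DOF catalog (3 rotations × two ankles, knees, hips,
wrists, elbows, shoulders + neck + waist) ships as editable JSON. Only
two entries are measured anchors (male sagittal hip 240.1 N·m and ankle
151.5 N·m); every other entry is a documented catalog default from the
adult strength literature, and the female catalog is the male one scaled
by the female/male group-mean knee ratio 107.6/212.4. Reference knee
torques default to those group means. Conclusions that depend on
non-anchor entries inherit their uncertainty.

### Numerical conventions

* Gravitational acceleration 9.81 m/s², configurable.
* All interval averages (COT, phase COT, component shares, stride-average
  MEE) use the composite trapezoid rule on the native sample grid, with
  linear interpolation at interval endpoints. On band-limited periodic
  signals over whole strides this is spectrally accurate; on smooth
  non-periodic sub-intervals it is second order (verified against a
  100×-resolution midpoint quadrature to better than 1e-8 relative at
  ~10^4 samples per stride).
* `heat_coefficients` clamps separable factors lying within `factor_tol`
  (default 1e-6, absolute) below zero to exactly zero instead of raising.
  Published weight estimates are printed to three significant figures, so
  a subject near the constraint boundary can evaluate marginally negative
  (order 1e-7) purely through rounding of the weights; treating that as a
  second-law violation would be spurious. Substantive violations raise
  with the offending DOFs and factor values.
* Angles are radians internally; degree conversion happens only in the
  motion-dialect reader when the file header declares degrees.

## Estimation

The measured quantity from calorimetry is a rate (W) while the integral
of the model rate over a stride is an energy (J); the residual is
therefore formed between the measurement and the *time-averaged* model
rate (integral divided by stride duration), which makes the objective
dimensionally consistent. The objective is half the mean squared residual
over all strides.

Given precomputed per-stride statistics (mean net power, per-DOF mean
|τ| and |τq̇|), the model's stride average is bilinear in the weights, so
objective and constraint gradients are analytic. The problem is solved by
sequential quadratic programming (SLSQP) on variables rescaled by each
weight's characteristic magnitude (the raw weights span 1e-5 to 1e3),
from multiple seeded starts: the packaged published weights, the zero
vector, and perturbations of both (default 8 starts; fixed default seed
20161228). Convergence tolerances: objective 1e-10, constraints 1e-8.

Constraints (all inequalities):

1. subject factors of both heat components ≥ 0 per estimation subject;
2. DOF factors ≥ 0, enforced at the extreme normalized reference torques
   per subject (the factor is affine in the reference torque, so the
   extremes bound all DOFs);
3. per-DOF work-plus-heat `τq̇ + h_am|τ| + h_sl|τq̇| ≥ 0`, aggregated as
   the minimum over all samples and strides per (subject, DOF) to keep
   the constraint count tractable (a per-stride mode is available);
4. when a subject's maximum aerobic power is known, the stride-average
   model rate lies in [0, VO2max]; otherwise skipped with a warning.

SQP iterates can terminate with constraint violations of order 1e-5.
Because the aggregated work-plus-heat margins and the subject factors are
exactly linear in the two intercept weights with non-negative
sensitivities, a deterministic restoration step raises the intercepts by
the worst deficit until every margin clears zero; the objective change is
of the order of the violation. Returned optima therefore satisfy all
margins to ≥ −1e-8, and a run whose best start cannot be restored fails
loudly with the constraint report.

The weight vector is not identifiable from average-rate data alone (the
model is overparameterized relative to the stride statistics), so
recovery is judged on predictions: on noiseless synthetic cohorts the
fitted model reproduces held-out subjects' average MEE to ~1e-14 %, and
under 5% multiplicative measurement noise the held-out mean absolute
error stays near the noise scale (~5%).

## Synthetic cohorts

The generator emulates the treadmill study design this model targets, not
any particular recording:

* **Subjects** — truncated normal draws (±3 SD, physiological floors) per
  sex from group statistics: males 1.83±0.06 m, 87.9±10.9 kg, 31±6 yr,
  212.4±66.2 N·m; females 1.62±0.07 m, 57.1±10.0 kg, 32±9 yr,
  107.6±35.7 N·m. Knee strength is drawn correlated with mass (ρ=0.7):
  strength tracks muscle mass, and uncorrelated draws produce subjects
  too weak to walk fast relative to their size. Sitting BMR is
  mass-proportional (1.05–1.15 W/kg) clipped to 60–110 W; VO2max is
  35–48 ml O₂/kg/min converted at 20.1 kJ/L.
* **Admissibility** — a drawn subject is rejected (and redrawn) if the
  ground-truth weights give it a negative heat factor (the model cannot
  have generated such a subject's data), if any `h_sl < 1` (which
  guarantees per-DOF work-plus-heat non-negativity for *any* kinematics,
  so the ground truth is feasible on every generated trial), or if its
  strength cap would truncate the lower-limb torques needed at the
  fastest condition.
* **Gait** — five speeds at 70/85/100/115/130% of a preferred speed
  (1.29±0.11 m/s) with stride length 1.48±0.11 m at preferred, scaling as
  √(v/v_pref). Angles are three-harmonic Fourier series per DOF (left =
  right shifted half a stride); the loaded joints' two-cycles-per-stride
  harmonic dominates and is phase-locked to the double-support midpoints
  (double knee flexion, rapid plantarflexion at push-off). Torques are
  harmonics plus two von-Mises bursts per stride — generation at push-off,
  absorption at loading response — whose signed powers cancel, plus a
  small velocity-proportional correction keeping net joint work near zero
  (steady-state walking dissipates). Amplitudes follow dynamic similarity
  (characteristic torque M·g·H/10) scaled by (v/v_pref)^0.95, capped at
  0.8 of the subject's scaled maximum. Events realize a double-support
  fraction falling linearly from 34.9% (slowest) to 22.1% (fastest);
  sampling is 120 Hz (overridable by a fixed samples-per-stride count).
* **Measurements** — the representative MEE per condition is the model
  rate under the ground-truth weights averaged over that condition's
  strides, times multiplicative Gaussian noise (default σ=3%; 3%
  stride-to-stride amplitude jitter, both separately configurable down to
  zero for idealized recovery studies). The estimation/validation split
  defaults to 8 + 4 subjects with 2 shared, mirroring the emulated
  protocol.

The free amplitude scales were calibrated once against published
physiology — total (gross) COT ≈ 0.33 at preferred speed with a convex
COT–speed curve whose minimum lies near the preferred speed, stride-average
MEE ≈ 4 W/kg, and double-support carrying a substantially larger share of
MEE than of cycle time — and then frozen as the defaults.

What the generator does *not* emulate: measured gait trajectory shapes
(harmonic templates, not recordings), soft-tissue and tendon dynamics,
kinematic measurement noise and marker artifacts (off by default),
within-subject adaptation across conditions, and non-periodic or
non-steady gait. Tests that pass on these cohorts demonstrate the
correctness and internal consistency of the pipeline and estimator, not
the biological fidelity of any particular coefficient value.

## Gait processing

Events: with vertical ground-reaction forces, contact is detected by a
20 N rising threshold with 5 N hysteresis and linear interpolation of the
crossing time; without forces, a foot-speed proxy marks stance where the
foot moves slower than 20% of its maximum speed. A stride runs right heel
strike to right heel strike (0% of the cycle at right heel strike);
double support spans heel strike of one side to toe-off of the other,
with instantaneous (zero-duration) double support allowed as the limiting
case. Bilateral synchronization divides a separately captured left stride
at the right heel strike it contains and resamples it periodically onto
the right-stride time base.

The COT–speed curve uses the three-term Laurent basis {1/v, 1, v} by
ordinary least squares — the minimal convex-capable form; convexity on
v > 0 is equivalent to c₋₁ > 0 and the interior minimum sits at
√(c₋₁/c₁). The Froude number is v/√(g·l) with leg length l = 0.53 H (the
square-root form is the dimensionless convention).

## Calorimetry

Gas exchange converts to watts either by the gas-exchange formula
(16.58·V̇O₂ + 4.51·V̇CO₂) kJ/min — the urinary-nitrogen term is dropped
because the protocol measures gases only — or by a fixed oxygen energy
equivalent (default 20.1 kJ/L O₂). The two agree within 3% for RER up to
~0.91 and within 5% across the aerobic band; an RER ≥ 1 flags the
conversion as invalid (anaerobic contribution) via a warning, not an
error. BMR is the mean of the last three of six rest minutes;
the representative MEE of a speed condition is the mean of the last three
of its five minutes (strict by default).

## Known limitations

* All non-anchor catalog torques are literature defaults; swap in
  measured values where available.
* The estimator's aggregated work-plus-heat constraint can admit isolated
  per-sample violations in the strict sense between the sampled minima of
  different strides; the per-stride mode tightens this at higher cost.
* Heat coefficients are constant per subject; fatigue, temperature and
  anaerobic pathways are out of scope, as is estimating maximum knee
  torque from anthropometrics.
* The generator's COT-curve shape near the domain edges depends on its
  calibrated speed exponents; it is a study-design emulator, not a gait
  simulator.
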