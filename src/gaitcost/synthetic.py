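"""Synthetic subjects, gait trials and metabolic records.

The generator emulates the statistical structure of a treadmill walking
energetics study: subjects drawn from published group anthropometrics
(sex-specific means and SDs of height, mass, age and maximum knee torque),
five speed conditions at 70/85/100/115/130% of a preferred speed near
1.29 m/s, periodic joint trajectories built from a few stride-frequency
harmonics, torque profiles with push-off bursts centred in the
double-support windows (emulating the concentration of joint power at the
step-to-step transition), a double-support fraction that decreases linearly
with speed from 34.9% at the slowest condition to 22.1% at the fastest, and
measured average MEE rates produced by evaluating the MEE-rate model with
ground-truth weights plus multiplicative measurement noise.

Everything is analytic (angles are finite Fourier series and velocities
their exact derivatives) and driven by one seeded random generator, so
datasets are reproducible bit-for-bit and ground truth is available for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .energetics import (
    HeatConstraintError,
    WeightParameters,
    heat_coefficients,
    mee_rate,
    published_weights,
)
from .estimation import ConditionEntry, EstimationDataset, _trapezoid_mean
from .subjects import DOFCatalog, SubjectProfile, default_catalog, scaled_max_torque
from .trial import HEEL_STRIKE, TOE_OFF, GaitEvent, GaitTrial

__all__ = ["GeneratorConfig", "generate_subject", "generate_gait_trial",
           "generate_dataset", "draw_gait_templates"]


#: Sex-specific subject-parameter distributions: (mean, sd) per field.
_SUBJECT_STATS = {
    "M": {"height_m": (1.83, 0.06), "mass_kg": (87.9, 10.9),
          "age_yr": (31.0, 6.0), "knee_max_torque_Nm": (212.4, 66.2)},
    "F": {"height_m": (1.62, 0.07), "mass_kg": (57.1, 10.0),
          "age_yr": (32.0, 9.0), "knee_max_torque_Nm": (107.6, 35.7)},
}
#: Physiological floors for truncated draws.
_FLOORS = {"height_m": 1.30, "mass_kg": 35.0, "age_yr": 18.0, "knee_max_torque_Nm": 40.0}

#: Joint-type motion templates: angle amplitude (rad), mean angle (rad),
#: peak-torque fraction of the subject's maximum at preferred speed, and the
#: relative weight of the push-off burst in the torque profile.
_JOINT_TEMPLATES = {
    "hip": {"sagi": (0.35, 0.0, 0.50, 0.6), "fron": (0.10, 0.0, 0.14, 0.3),
            "tran": (0.08, 0.0, 0.10, 0.2)},
    "knee": {"sagi": (0.55, 0.45, 0.45, 0.6), "fron": (0.05, 0.0, 0.10, 0.3),
             "tran": (0.05, 0.0, 0.08, 0.2)},
    "ankle": {"sagi": (0.30, 0.0, 0.45, 0.8), "fron": (0.08, 0.0, 0.12, 0.4),
              "tran": (0.06, 0.0, 0.10, 0.3)},
    "shoulder": {"sagi": (0.15, 0.0, 0.06, 0.0), "fron": (0.05, 0.0, 0.05, 0.0),
                 "tran": (0.05, 0.0, 0.04, 0.0)},
    "elbow": {"sagi": (0.20, 0.35, 0.06, 0.0), "fron": (0.05, 0.0, 0.04, 0.0),
              "tran": (0.05, 0.0, 0.03, 0.0)},
    "wrist": {"sagi": (0.08, 0.0, 0.03, 0.0), "fron": (0.05, 0.0, 0.03, 0.0),
              "tran": (0.04, 0.0, 0.02, 0.0)},
    "neck": {"sagi": (0.05, 0.0, 0.05, 0.0), "fron": (0.04, 0.0, 0.04, 0.0),
             "tran": (0.06, 0.0, 0.04, 0.0)},
    "waist": {"sagi": (0.06, 0.0, 0.10, 0.2), "fron": (0.05, 0.0, 0.09, 0.2),
              "tran": (0.08, 0.0, 0.06, 0.2)},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated protocol: 8 estimation subjects (even
    sex mix), 4 validation subjects of which 2 are shared with the
    estimation group, five speed conditions as percentages of a preferred
    speed of 1.29 +/- 0.11 m/s with stride length 1.48 +/- 0.11 m at the
    preferred speed, double-support fraction falling linearly from 34.9% at
    the slowest to 22.1% at the fastest condition, kinematics sampled at
    120 Hz, and 3% multiplicative Gaussian noise on the measured average
    MEE rates.  ``torque_scale`` is a single global gain on all joint
    torques, calibrated so the male-mean subject's total cost of transport
    at the preferred speed lands near published walking values (~0.33).
    """

    seed: int = 0
    n_estimation_subjects: int = 8
    n_validation_subjects: int = 4
    n_shared_validation: int = 2
    male_fraction: float = 0.5
    speed_conditions_pct: tuple[float, ...] = (70.0, 85.0, 100.0, 115.0, 130.0)
    preferred_speed_mps: tuple[float, float] = (1.29, 0.11)
    stride_length_m: tuple[float, float] = (1.48, 0.11)
    ds_fraction_anchors_pct: tuple[float, float] = (34.9, 22.1)
    bmr_range_W: tuple[float, float] = (60.0, 110.0)
    strength_mass_correlation: float = 0.7
    vo2max_range_ml_kg_min: tuple[float, float] = (35.0, 48.0)
    n_harmonics: int = 3
    torque_scale: float = 0.65
    torque_speed_exponent: float = 0.95
    velocity_scale: float = 1.5
    net_work_fraction: float = 0.1
    stride_length_exponent: float = 0.5
    speed_ripple_amplitude: float = 0.03
    speed_ripple_cycles: int = 2
    pushoff_concentration: float = 15.0
    burst_gain: float = 5.0
    sample_rate_hz: float = 120.0
    samples_per_stride: Optional[int] = None
    strides_per_condition: int = 2
    mee_noise_sd: float = 0.03
    stride_jitter: float = 0.03
    with_grf: bool = False
    grf_ramp_s: float = 0.02
    ground_truth_weights: WeightParameters = field(default_factory=published_weights)

    def __post_init__(self) -> None:
        lo, hi = self.ds_fraction_anchors_pct
        if not (0 < lo < 50 and 0 < hi < 50):
            raise ValueError("DS fraction anchors must lie in (0, 50)%")
        if self.mee_noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    def ds_fraction_pct(self, speed_pct: float) -> float:
        """Linear interpolation of DS fraction between the speed anchors."""
        lo_pct, hi_pct = min(self.speed_conditions_pct), max(self.speed_conditions_pct)
        a, b = self.ds_fraction_anchors_pct
        if hi_pct == lo_pct:
            return a
        frac = (speed_pct - lo_pct) / (hi_pct - lo_pct)
        return a + (b - a) * frac


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    if sd == 0:
        return mean
    lo = max(mean - 3 * sd, floor)
    hi = mean + 3 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_subject(config: GeneratorConfig, rng: np.random.Generator,
                     sex: Optional[str] = None, subject_id: str = "S") -> SubjectProfile:
    """Draw one subject from the sex-specific truncated-normal distributions.

    BMR is uniform on the configured range; VO2max is drawn in ml O2/kg/min
    and converted to watts at 20.1 kJ per liter O2.
    """
    if sex is None:
        sex = "M" if rng.random() < config.male_fraction else "F"
    s = _SUBJECT_STATS[sex]
    vals = {k: _truncated_normal(rng, *s[k], _FLOORS[k])
            for k in ("height_m", "mass_kg", "age_yr")}
    # maximum strength correlates with body mass (muscle mass scales with
    # body size): correlated truncated-normal draw
    rho = config.strength_mass_correlation
    m_mean, m_sd = s["mass_kg"]
    t_mean, t_sd = s["knee_max_torque_Nm"]
    z_mass = (vals["mass_kg"] - m_mean) / m_sd if m_sd > 0 else 0.0
    z = rho * z_mass + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
    vals["knee_max_torque_Nm"] = float(np.clip(
        t_mean + t_sd * z, max(_FLOORS["knee_max_torque_Nm"], t_mean - 3 * t_sd),
        t_mean + 3 * t_sd,
    ))
    # sitting BMR scales with body mass (~1.0-1.2 W/kg), clipped to the
    # configured absolute range
    bmr = float(np.clip(vals["mass_kg"] * rng.uniform(1.05, 1.15), *config.bmr_range_W))
    vo2_ml = float(rng.uniform(*config.vo2max_range_ml_kg_min))
    vo2max_W = vo2_ml * vals["mass_kg"] / 1000.0 * 20.1e3 / 60.0
    return SubjectProfile(
        id=subject_id, sex=sex, bmr_W=bmr, vo2max_W=vo2max_W, **vals
    )


def _dof_template(dof_id: str) -> tuple[float, float, float, float]:
    joint = dof_id.split("_")[-2] if "_" in dof_id else dof_id
    axis = dof_id.split("_")[-1]
    return _JOINT_TEMPLATES[joint][axis]


def _pushoff_bump(phase: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Smooth periodic bump (von Mises shape) centred at ``center`` in [0,1)."""
    return np.exp(kappa * (np.cos(2 * np.pi * (phase - center)) - 1.0))


def draw_gait_templates(catalog: DOFCatalog, config: GeneratorConfig,
                        rng: np.random.Generator) -> dict[str, dict]:
    """Draw one harmonic gait template per right/central DOF.

    A subject's templates are reused across speed conditions (the pattern is
    the subject's; speed scales its frequency and torque amplitude), and the
    left mirror of a paired DOF reuses its right template at a half-stride
    phase shift.
    """
    K = config.n_harmonics
    ks = np.arange(1, K + 1)
    # nominal DS midpoint used to anchor the second harmonic's phase
    d_nom = 0.5 * np.mean(config.ds_fraction_anchors_pct) / 100.0
    templates: dict[str, dict] = {}
    for dof in catalog.dofs:
        if dof.side == "left":
            continue
        amp, mean_q, peak_frac, burst = _dof_template(dof.dof_id)
        q_amp = config.velocity_scale * amp * rng.uniform(0.9, 1.1, K) / ks
        q_phi = rng.uniform(0, 2 * np.pi, K)
        if burst > 0 and K >= 2:
            # joints loaded at the step-to-step transition move fastest
            # there (double flexion / rapid plantarflexion at push-off):
            # the two-cycles-per-stride harmonic strongly dominates, and
            # its phase is locked to the double-support midpoints at
            # generation time
            q_amp[1] *= 1.4
            q_amp[::2] *= 0.35
        templates[dof.dof_id] = {
            "q_amp": q_amp,
            "q_phi": q_phi,
            "t_amp": rng.uniform(0.7, 1.0, K) / ks,
            "t_phi": rng.uniform(0, 2 * np.pi, K),
            "mean_q": mean_q,
            "peak_frac": peak_frac * rng.uniform(0.9, 1.1),
            "burst": burst,
        }
    return templates


def generate_gait_trial(
    subject: SubjectProfile,
    speed_pct: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    catalog: Optional[DOFCatalog] = None,
    preferred_speed_mps: Optional[float] = None,
    stride_length_pref_m: Optional[float] = None,
    n_strides: int = 1,
    templates: Optional[dict[str, dict]] = None,
) -> GaitTrial:
    """Generate one periodic synthetic trial at a percent-of-preferred speed.

    Joint angles are finite Fourier series at the stride frequency with the
    exact analytic velocity; torques are harmonic series plus a push-off
    burst centred in the double-support window, scaled so the peak stays
    below 0.8 of the subject's maximum; left-side channels equal the
    right-side ones shifted by half a stride.  Events realize the
    configured double-support fraction exactly.
    """
    catalog = catalog or default_catalog(subject.sex)
    v_pref = preferred_speed_mps if preferred_speed_mps is not None \
        else config.preferred_speed_mps[0]
    L_pref = stride_length_pref_m if stride_length_pref_m is not None \
        else config.stride_length_m[0]
    v = v_pref * speed_pct / 100.0
    L = L_pref * (v / v_pref) ** config.stride_length_exponent
    T = L / v  # stride period, s

    if config.samples_per_stride is not None:
        nps = int(config.samples_per_stride)
    else:
        nps = max(int(round(T * config.sample_rate_hz)), 8)
    n = nps * n_strides
    t = np.linspace(0.0, T * n_strides, n + 1)
    phase = np.mod(t / T, 1.0)

    ds_frac = config.ds_fraction_pct(speed_pct) / 100.0
    d = ds_frac / 2.0  # each DS phase, fraction of stride

    speed_gain = (v / v_pref) ** config.torque_speed_exponent
    omega = 2 * np.pi / T
    K = config.n_harmonics

    n_dofs = catalog.n
    q = np.empty((n + 1, n_dofs))
    qd = np.empty((n + 1, n_dofs))
    tau = np.empty((n + 1, n_dofs))

    # harmonic templates: one per right/central DOF; the left mirror reuses
    # its right template at phase + 1/2, so mirrored channels are exact
    # half-stride shifts of each other
    if templates is None:
        templates = draw_gait_templates(catalog, config, rng)
    ks = np.arange(1, K + 1)
    ph_ref = np.linspace(0.0, 1.0, 2048, endpoint=False)

    # lock the two-cycles-per-stride harmonic of burst joints so |qd| peaks
    # at the midpoints of both double-support windows of *this* trial
    if K >= 2:
        locked = {}
        for bid, p in templates.items():
            if p["burst"] > 0:
                p = dict(p)
                q_phi = p["q_phi"].copy()
                q_phi[1] = np.pi / 2 - 4 * np.pi * (0.5 + d / 2)
                p["q_phi"] = q_phi
            locked[bid] = p
        templates = locked

    def qd_shape(ph: np.ndarray, p: dict) -> np.ndarray:
        ang = 2 * np.pi * np.outer(ph, ks)
        return -(np.sin(ang + p["q_phi"]) * (ks * omega)) @ p["q_amp"]

    def tau_shape(ph: np.ndarray, p: dict, r: float, alpha: float) -> np.ndarray:
        # harmonics plus two double-support bursts: energy generation at
        # push-off (just before the side's toe-off) and absorption at
        # loading response (just after its heel strike) -- joint kinetics
        # concentrate at the step-to-step transition, with the two bursts'
        # signed power nearly cancelling, as in steady gait.  alpha removes
        # the residual net work through a velocity-proportional component.
        ang = 2 * np.pi * np.outer(ph, ks)
        s = np.cos(ang + p["t_phi"]) @ p["t_amp"]
        if p["burst"] > 0:
            s = 0.5 * s + p["burst"] * config.burst_gain * (
                _pushoff_bump(ph, 0.5 + d / 2, config.pushoff_concentration)
                - r * _pushoff_bump(ph, d / 2, config.pushoff_concentration)
            )
        return s - alpha * qd_shape(ph, p)

    # per-template constants, computed on a reference phase grid so mirrored
    # sides get identical scaling
    consts: dict[str, tuple[float, float, float]] = {}
    for bid, p in templates.items():
        qd_ref = qd_shape(ph_ref, p)
        if p["burst"] > 0:
            b1 = _pushoff_bump(ph_ref, 0.5 + d / 2, config.pushoff_concentration)
            b2 = _pushoff_bump(ph_ref, d / 2, config.pushoff_concentration)
            p1, p2 = float(np.mean(b1 * qd_ref)), float(np.mean(b2 * qd_ref))
            r = p1 / p2 if abs(p2) > 1e-12 else 0.0
            r = float(np.clip(r, -5.0, 5.0))
        else:
            r = 0.0
        raw = tau_shape(ph_ref, p, r, 0.0)
        mean_qd2 = float(np.mean(qd_ref**2))
        alpha = 0.0
        if mean_qd2 > 0:
            alpha = (1.0 - config.net_work_fraction) * float(
                np.mean(raw * qd_ref)
            ) / mean_qd2
        peak = float(np.max(np.abs(tau_shape(ph_ref, p, r, alpha))))
        consts[bid] = (r, alpha, peak)

    # walking torques follow dynamic similarity (characteristic torque
    # M*g*H/10), capped by the subject's strength at 0.8 of maximum
    tau_unit = subject.mass_kg * 9.81 * subject.height_m / 10.0
    for j, dof in enumerate(catalog.dofs):
        base_id = dof.mirror_of if dof.side == "left" else dof.dof_id
        p = templates[base_id]
        r, alpha, peak = consts[base_id]
        ph = phase + 0.5 if dof.side == "left" else phase
        ang = 2 * np.pi * np.outer(ph, ks)  # (n+1, K)
        q[:, j] = p["mean_q"] + (np.cos(ang + p["q_phi"]) @ p["q_amp"])
        qd[:, j] = qd_shape(ph, p)
        tau_max = scaled_max_torque(subject, catalog, dof.dof_id)
        target = min(
            config.torque_scale * p["peak_frac"] * speed_gain * tau_unit,
            0.8 * tau_max,
        )
        tau[:, j] = tau_shape(ph, p, r, alpha) / peak * target

    ripple = config.speed_ripple_amplitude * np.sin(
        2 * np.pi * config.speed_ripple_cycles * phase
    )
    v_trace = v * (1.0 + ripple)

    events = []
    for k in range(n_strides):
        t0 = k * T
        events += [
            GaitEvent(t0, "right", HEEL_STRIKE),
            GaitEvent(t0 + d * T, "left", TOE_OFF),
            GaitEvent(t0 + 0.5 * T, "left", HEEL_STRIKE),
            GaitEvent(t0 + (0.5 + d) * T, "right", TOE_OFF),
        ]
    events.append(GaitEvent(n_strides * T, "right", HEEL_STRIKE))

    meta = {
        "speed_pct": speed_pct,
        "speed_mps": v,
        "stride_time_s": T,
        "stride_length_m": L,
        "ds_fraction_pct": ds_frac * 100.0,
        "subject_id": subject.id,
    }
    if config.with_grf:
        meta["grf"] = _grf_traces(t, T, d, subject.mass_kg, n_strides, config.grf_ramp_s)

    return GaitTrial(t=t, q=q, qd=qd, tau=tau, v=v_trace,
                     dof_ids=catalog.dof_ids, events=tuple(events), meta=meta)


def _grf_traces(t: np.ndarray, T: float, d: float, mass_kg: float,
                n_strides: int, ramp_s: float) -> dict[str, np.ndarray]:
    """Vertical GRF per side: body weight during stance, linear edges."""
    bw = mass_kg * 9.81

    def side_force(hs_phase: float, to_phase: float) -> np.ndarray:
        f = np.zeros_like(t)
        for k in range(n_strides):
            hs = (k + hs_phase) * T
            to = (k + to_phase) * T
            f += np.clip((t - hs) / ramp_s, 0, 1) * np.clip((to - t) / ramp_s, 0, 1) * bw
        return f

    # right stance: [0, 0.5 + d]; left stance: [0.5, 1 + d] (wraps, so also [-0.5, d])
    right = side_force(0.0, 0.5 + d)
    left = side_force(0.5, 1.0 + d) + side_force(-0.5, d)
    return {"right": right, "left": left}


def _strength_sufficient(subject: SubjectProfile, catalog: DOFCatalog,
                         config: GeneratorConfig) -> bool:
    """Can the subject deliver the top-speed walking torques within 0.8 max?

    The protocol requires walking at the fastest condition; a subject whose
    strength cap would truncate the required lower-limb sagittal torques
    there cannot complete it and is rejected from the cohort.
    """
    tau_unit = subject.mass_kg * 9.81 * subject.height_m / 10.0
    gain = (max(config.speed_conditions_pct) / 100.0) ** config.torque_speed_exponent
    for joint in ("hip", "knee", "ankle"):
        pf = _JOINT_TEMPLATES[joint]["sagi"][2] * 1.1  # worst-case jitter
        need = config.torque_scale * pf * gain * tau_unit
        have = 0.8 * scaled_max_torque(subject, catalog, f"r_{joint}_sagi")
        if have < need:
            return False
    return True


def _jitter_templates(templates: dict[str, dict], rng: np.random.Generator,
                      rel: float) -> dict[str, dict]:
    """Small stride-to-stride multiplicative variation of a subject's templates."""
    out = {}
    for bid, p in templates.items():
        q = dict(p)
        q["q_amp"] = p["q_amp"] * (1 + rel * rng.standard_normal(len(p["q_amp"])))
        q["t_amp"] = p["t_amp"] * (1 + rel * rng.standard_normal(len(p["t_amp"])))
        out[bid] = q
    return out


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[EstimationDataset, EstimationDataset, dict]:
    """Generate matched estimation and validation datasets plus ground truth.

    Measured average MEE rates come from evaluating the MEE-rate model with
    the ground-truth weights on each stride, averaging over the condition's
    strides, and applying multiplicative Gaussian noise.  The validation
    group mixes subjects shared with the estimation group and unseen ones,
    mirroring the emulated protocol.  Ground truth (weights, noiseless
    per-condition averages, subject list) is returned for oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    catalogs = {"M": default_catalog("M"), "F": default_catalog("F")}
    w_true = config.ground_truth_weights

    n_total = config.n_estimation_subjects + config.n_validation_subjects \
        - config.n_shared_validation
    subjects = []
    for i in range(n_total):
        sex = "M" if i % 2 == 0 else "F" if config.male_fraction == 0.5 else None
        # the cohort must be admissible under the ground-truth model (heat
        # coefficients non-negative) and strong enough to complete the
        # fastest walking condition
        for _ in range(200):
            subj = generate_subject(config, rng, sex=sex, subject_id=f"S{i + 1:02d}")
            try:
                h = heat_coefficients(w_true, subj, catalogs[subj.sex])
            except HeatConstraintError:
                continue
            # h_sl >= 1 everywhere guarantees the per-DOF non-negativity of
            # work plus heat for any kinematics, so the ground-truth model
            # is feasible on every generated trial
            if np.min(h.h_sl) < 1.0:
                continue
            if _strength_sufficient(subj, catalogs[subj.sex], config):
                break
        else:
            raise RuntimeError("could not draw an admissible subject in 200 tries")
        subjects.append(subj)
    est_subjects = subjects[: config.n_estimation_subjects]
    val_subjects = (
        est_subjects[: config.n_shared_validation]
        + subjects[config.n_estimation_subjects:]
    )

    truth_rows = []

    def build_entries(group: list[SubjectProfile]) -> list[ConditionEntry]:
        entries = []
        for subj in group:
            catalog = catalogs[subj.sex]
            h = heat_coefficients(w_true, subj, catalog)
            v_pref = _truncated_normal(rng, *config.preferred_speed_mps, 0.6)
            L_pref = _truncated_normal(rng, *config.stride_length_m, 0.8)
            templates = draw_gait_templates(catalog, config, rng)
            for pct in config.speed_conditions_pct:
                trials = [
                    generate_gait_trial(
                        subj, pct, config, rng, catalog=catalog,
                        preferred_speed_mps=v_pref, stride_length_pref_m=L_pref,
                        templates=_jitter_templates(templates, rng, config.stride_jitter),
                    )
                    for _ in range(config.strides_per_condition)
                ]
                avgs = [
                    float(_trapezoid_mean(tr.t, mee_rate(tr, h, subj.bmr_W).e_met))
                    for tr in trials
                ]
                clean = float(np.mean(avgs))
                noise = 1.0 + config.mee_noise_sd * rng.standard_normal()
                measured = clean * max(noise, 0.5)
                entries.append(ConditionEntry(
                    subject=subj, condition=f"{subj.id}-{pct:g}pct",
                    speed_mps=trials[0].meta["speed_mps"],
                    trials=trials, measured_mee_W=measured,
                ))
                truth_rows.append({
                    "subject": subj.id, "speed_pct": pct,
                    "noiseless_mee_W": clean, "measured_mee_W": measured,
                    "stride_averages_W": avgs,
                })
        return entries

    est = EstimationDataset(entries=build_entries(est_subjects), catalog_by_sex=catalogs)
    val = EstimationDataset(entries=build_entries(val_subjects), catalog_by_sex=catalogs)
    ground_truth = {
        "weights": w_true,
        "rows": truth_rows,
        "estimation_subject_ids": [s.id for s in est_subjects],
        "validation_subject_ids": [s.id for s in val_subjects],
    }
    return est, val, ground_truth
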