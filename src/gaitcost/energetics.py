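"""Metabolic energy expenditure (MEE) rate, ICOT, and cost of transport.

The instantaneous whole-body MEE rate is modeled in joint space as

    E_met(t) = sum_i tau_i qd_i                   (net joint work rate)
             + sum_i h_am[i] |tau_i|              (activation-maintenance heat)
             + sum_i h_sl[i] |tau_i qd_i|         (shortening-lengthening heat)
             + sum_i Qcc_i(t)                     (torque-independent cocontraction heat)
             + E_bmr                              (basal metabolic rate)

with subject- and DOF-specific heat coefficients built from two separable
factors: a subject factor, linear in normalized mass, age and height, and a
DOF factor, affine in the strength-scaled normalized reference torque:

    h[i] = (w0 + w1*m_n + w2*a_n + w3*h_n) * (1 + w4 * r * tau_n[i])

where ``r`` is the subject's knee strength ratio.  The second law requires
``h[i] >= 0``; both factors are constrained non-negative.

The dimensionless instantaneous cost of transport is
``ICOT(t) = E_met(t) / (M g v(t))``, and the cost of transport over an
interval T is the time-averaged MEE rate divided by ``M g`` times the
time-averaged speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .subjects import (
    DOFCatalog,
    NormalizedParameters,
    SubjectProfile,
    ValidationError,
    normalize_parameters,
)
from .trial import GaitTrial

__all__ = [
    "WeightParameters",
    "HeatCoefficients",
    "EnergeticsTrace",
    "HeatConstraintError",
    "published_weights",
    "heat_coefficients",
    "activation_maintenance_heat",
    "shortening_lengthening_heat",
    "mee_rate",
    "icot",
    "cot",
    "component_breakdown",
    "interval_average",
    "GRAVITY",
]

#: Standard gravitational acceleration (m/s^2); configurable per call.
GRAVITY = 9.81


class HeatConstraintError(ValidationError):
    """A heat coefficient would be negative (second-law violation)."""


@dataclass(frozen=True)
class WeightParameters:
    """The ten regression weights of the separable heat-coefficient model.

    ``am`` weights (w0..w4) build the activation-maintenance coefficient,
    ``sl`` weights the shortening-lengthening coefficient.  The weights act
    on *normalized* subject parameters (mass/100, age/100, height/10,
    reference torque/100); ``scales`` records that convention.
    """

    am: tuple[float, ...]
    sl: tuple[float, ...]
    scales: dict = field(
        default_factory=lambda: {"mass": 100.0, "age": 100.0, "height": 10.0, "torque": 100.0}
    )
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "am", tuple(float(x) for x in self.am))
        object.__setattr__(self, "sl", tuple(float(x) for x in self.sl))
        if len(self.am) != 5 or len(self.sl) != 5:
            raise ValidationError("weights must have 5 'am' and 5 'sl' entries")
        if not all(np.isfinite(self.am + self.sl)):
            raise ValidationError("weights must be finite")

    @property
    def vector(self) -> np.ndarray:
        """The weights as the flat 10-vector [am(5), sl(5)]."""
        return np.array(self.am + self.sl, dtype=float)

    @classmethod
    def from_vector(cls, w: Sequence[float], provenance: str = "estimate") -> "WeightParameters":
        w = tuple(float(x) for x in w)
        if len(w) != 10:
            raise ValidationError("weight vector must have 10 entries")
        return cls(am=w[:5], sl=w[5:], provenance=provenance)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"am": list(self.am), "sl": list(self.sl), "scales": self.scales,
                 "provenance": self.provenance},
                fh, indent=1,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "WeightParameters":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(am=d["am"], sl=d["sl"], scales=d.get("scales", {}),
                   provenance=d.get("provenance", str(path)))


def published_weights() -> WeightParameters:
    """The packaged published estimate of the ten weight parameters."""
    with resources.files("gaitcost.data").joinpath("published_weights.json").open(
        "r", encoding="utf-8"
    ) as fh:
        d = json.load(fh)
    return WeightParameters(am=d["am"], sl=d["sl"], scales=d["scales"],
                            provenance=d["provenance"])


@dataclass(frozen=True)
class HeatCoefficients:
    """Per-DOF heat coefficients for one subject.

    ``h_am`` has units 1/s (it multiplies a torque to give watts); ``h_sl``
    is dimensionless (it multiplies a mechanical power).  Both are
    non-negative by construction.
    """

    h_am: np.ndarray
    h_sl: np.ndarray
    dof_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "h_am", np.asarray(self.h_am, dtype=float))
        object.__setattr__(self, "h_sl", np.asarray(self.h_sl, dtype=float))
        if self.h_am.shape != (len(self.dof_ids),) or self.h_sl.shape != (len(self.dof_ids),):
            raise ValidationError("coefficient arrays must be one value per DOF")
        if np.any(self.h_am < 0) or np.any(self.h_sl < 0):
            bad = [self.dof_ids[i] for i in
                   np.nonzero((self.h_am < 0) | (self.h_sl < 0))[0]]
            raise HeatConstraintError(f"negative heat coefficient at DOFs {bad}")


def coefficient_factors(
    w: WeightParameters, norm: NormalizedParameters
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """The separable factors (subject factor, per-DOF factor) for am and sl."""
    tau_n = np.asarray(norm.tau_n)
    f_am = w.am[0] + w.am[1] * norm.m_n + w.am[2] * norm.a_n + w.am[3] * norm.h_n
    s_am = 1.0 + w.am[4] * norm.strength_ratio * tau_n
    f_sl = w.sl[0] + w.sl[1] * norm.m_n + w.sl[2] * norm.a_n + w.sl[3] * norm.h_n
    s_sl = 1.0 + w.sl[4] * norm.strength_ratio * tau_n
    return f_am, s_am, f_sl, s_sl


def heat_coefficients(
    w: WeightParameters,
    subject: SubjectProfile,
    catalog: DOFCatalog,
    factor_tol: float = 1e-6,
) -> HeatCoefficients:
    """Evaluate the separable heat-coefficient model for one subject.

    Factors within ``factor_tol`` below zero are clamped to exactly zero:
    published weight estimates are printed to few significant figures, so a
    subject near the constraint boundary can evaluate marginally negative
    purely through rounding of the weights.  Substantive violations (beyond
    the tolerance) raise :class:`HeatConstraintError` listing the offending
    DOFs and factor values.
    """
    norm = normalize_parameters(subject, catalog)
    f_am, s_am, f_sl, s_sl = coefficient_factors(w, norm)

    def _clamp_scalar(x: float, name: str) -> float:
        if x < -factor_tol:
            raise HeatConstraintError(f"{name} subject factor = {x:.3e} < 0")
        return max(x, 0.0)

    def _clamp_vec(x: np.ndarray, name: str) -> np.ndarray:
        if np.any(x < -factor_tol):
            bad = np.nonzero(x < -factor_tol)[0]
            detail = ", ".join(f"{catalog.dofs[i].dof_id}: {x[i]:.3e}" for i in bad)
            raise HeatConstraintError(f"{name} DOF factor < 0 at [{detail}]")
        return np.maximum(x, 0.0)

    f_am = _clamp_scalar(f_am, "activation-maintenance")
    f_sl = _clamp_scalar(f_sl, "shortening-lengthening")
    s_am = _clamp_vec(s_am, "activation-maintenance")
    s_sl = _clamp_vec(s_sl, "shortening-lengthening")
    return HeatCoefficients(h_am=f_am * s_am, h_sl=f_sl * s_sl, dof_ids=catalog.dof_ids)


def activation_maintenance_heat(h_am: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Per-DOF activation-maintenance heat rate trace ``h_am[i] |tau_i(t)|`` (W)."""
    h_am = np.asarray(h_am, dtype=float)
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    if tau.shape[1] != h_am.shape[0]:
        raise ValidationError(
            f"torque trace has {tau.shape[1]} DOFs but {h_am.shape[0]} coefficients given"
        )
    return h_am[None, :] * np.abs(tau)


def shortening_lengthening_heat(h_sl: np.ndarray, tau: np.ndarray, qd: np.ndarray) -> np.ndarray:
    """Per-DOF shortening-lengthening heat rate trace ``h_sl[i] |tau_i qd_i|`` (W)."""
    h_sl = np.asarray(h_sl, dtype=float)
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    qd = np.atleast_2d(np.asarray(qd, dtype=float))
    if tau.shape != qd.shape:
        raise ValidationError(f"tau shape {tau.shape} != qd shape {qd.shape}")
    if tau.shape[1] != h_sl.shape[0]:
        raise ValidationError(
            f"traces have {tau.shape[1]} DOFs but {h_sl.shape[0]} coefficients given"
        )
    return h_sl[None, :] * np.abs(tau * qd)


@dataclass
class EnergeticsTrace:
    """Per-sample energy components of one trial.

    ``e_met = work_rate + q_am + q_sl + q_cc + bmr`` holds at every sample;
    ``per_dof_e_met`` attributes work plus both heat terms to each DOF (BMR
    and cocontraction are unattributed pools).
    """

    t: np.ndarray
    work_rate: np.ndarray
    q_am: np.ndarray
    q_sl: np.ndarray
    q_cc: np.ndarray
    bmr_W: float
    e_met: np.ndarray
    per_dof_e_met: np.ndarray
    v: np.ndarray
    dof_ids: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]


def mee_rate(trial: GaitTrial, h: HeatCoefficients, bmr_W: float) -> EnergeticsTrace:
    """Evaluate the instantaneous MEE-rate model on a trial.

    Returns the per-sample work rate, heat components, their total
    ``e_met(t)`` and the per-DOF attribution.  A negative cocontraction
    input violates the second law and raises.
    """
    if tuple(trial.dof_ids) != tuple(h.dof_ids):
        raise ValidationError("trial and coefficients disagree on DOF ordering")
    if bmr_W < 0:
        raise ValidationError("bmr_W must be >= 0")
    qcc = trial.qcc_or_zero()
    if np.any(qcc < 0):
        raise ValidationError("cocontraction heat must be non-negative (second law)")

    power = trial.tau * trial.qd
    q_am_dof = activation_maintenance_heat(h.h_am, trial.tau)
    q_sl_dof = shortening_lengthening_heat(h.h_sl, trial.tau, trial.qd)
    per_dof = power + q_am_dof + q_sl_dof
    work_rate = power.sum(axis=1)
    q_am = q_am_dof.sum(axis=1)
    q_sl = q_sl_dof.sum(axis=1)
    q_cc = qcc.sum(axis=1)
    e_met = work_rate + q_am + q_sl + q_cc + bmr_W
    return EnergeticsTrace(
        t=trial.t.copy(),
        work_rate=work_rate,
        q_am=q_am,
        q_sl=q_sl,
        q_cc=q_cc,
        bmr_W=float(bmr_W),
        e_met=e_met,
        per_dof_e_met=per_dof,
        v=trial.v.copy(),
        dof_ids=trial.dof_ids,
        meta=dict(trial.meta),
    )


def icot(
    trace: EnergeticsTrace,
    subject: SubjectProfile,
    v: Optional[np.ndarray] = None,
    g: float = GRAVITY,
) -> np.ndarray:
    """Instantaneous cost of transport ``E_met(t) / (M g v(t))``, pointwise.

    ``v`` defaults to the speed stored on the trace.  Raises on any
    non-positive speed sample, reporting its index.
    """
    v = trace.v if v is None else np.asarray(v, dtype=float)
    if v.shape != trace.e_met.shape:
        raise ValidationError("speed trace shape mismatch")
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        raise ValidationError(f"non-positive speed at sample index {int(bad[0])}")
    return trace.e_met / (subject.mass_kg * g * v)


def interval_average(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    """Time-average of a sampled trace over [t0, t1].

    Composite trapezoid on the native grid, with linear interpolation at the
    interval endpoints.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (t[0] - 1e-12 <= t0 < t1 <= t[-1] + 1e-12):
        raise ValidationError(f"interval [{t0}, {t1}] outside trace [{t[0]}, {t[-1]}]")
    t0 = max(t0, float(t[0]))
    t1 = min(t1, float(t[-1]))
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    yy = np.concatenate([[np.interp(t0, t, y)], y[inside], [np.interp(t1, t, y)]])
    return float(np.trapezoid(yy, tt) / (t1 - t0))


def cot(
    trace: EnergeticsTrace,
    interval: tuple[float, float],
    subject: SubjectProfile,
    g: float = GRAVITY,
) -> float:
    """Cost of transport over a time interval.

    Time-averaged MEE rate divided by ``M g`` times the time-averaged speed,
    both averages by trapezoidal integration on the sample grid.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if not t1 > t0:
        raise ValidationError("interval must have positive duration")
    e_avg = interval_average(trace.t, trace.e_met, t0, t1)
    v_avg = interval_average(trace.t, trace.v, t0, t1)
    if v_avg <= 0:
        raise ValidationError("mean speed over interval must be positive")
    return e_avg / (subject.mass_kg * g * v_avg)


def component_breakdown(
    trace: EnergeticsTrace, interval: Optional[tuple[float, float]] = None
) -> dict:
    """Interval integrals (J) and shares (%) of each MEE component.

    Shares are of the total MEE integral over the interval and sum to 100%.
    """
    t0 = float(trace.t[0]) if interval is None else float(interval[0])
    t1 = float(trace.t[-1]) if interval is None else float(interval[1])
    duration = t1 - t0
    if duration <= 0:
        raise ValidationError("interval must have positive duration")
    comps = {
        "work": trace.work_rate,
        "q_am": trace.q_am,
        "q_sl": trace.q_sl,
        "q_cc": trace.q_cc,
        "bmr": np.full_like(trace.e_met, trace.bmr_W),
    }
    integrals = {k: interval_average(trace.t, y, t0, t1) * duration for k, y in comps.items()}
    total = interval_average(trace.t, trace.e_met, t0, t1) * duration
    shares = {k: 100.0 * v / total for k, v in integrals.items()}
    return {
        "interval_s": (t0, t1),
        "integrals_J": integrals,
        "total_J": total,
        "shares_pct": shares,
    }
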