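"""Gait-cycle processing: events, phases, synchronization, COT curves.

A stride runs from a right heel strike to the next right heel strike (0% of
the gait cycle at right heel strike).  Double support (DS) spans heel strike
of one side to toe-off of the other; the remainder of the cycle is single
support (SS), labelled by the stance side.  Phase-specific cost of transport
integrates the MEE-rate model over the union of SS or DS intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import GRAVITY, EnergeticsTrace, interval_average
from .subjects import SubjectProfile, ValidationError
from .trial import HEEL_STRIKE, TOE_OFF, GaitEvent, GaitTrial

__all__ = [
    "Phase",
    "PhaseSegmentation",
    "COTCurve",
    "detect_gait_events",
    "segment_phases",
    "synchronize_bilateral",
    "froude_number",
    "fit_cot_curve",
    "phase_cot",
    "parameter_correlations",
]


@dataclass(frozen=True)
class Phase:
    label: str  # {"SS_left", "SS_right", "DS1", "DS2"}
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSegmentation:
    """Strides and their SS/DS phases.

    Phases within a stride are contiguous and non-overlapping; their
    durations sum to the stride duration.  Each complete stride contains
    exactly two DS phases.
    """

    strides: tuple[tuple[float, float], ...]
    phases: tuple[Phase, ...]

    def phases_in_stride(self, k: int) -> tuple[Phase, ...]:
        s0, s1 = self.strides[k]
        return tuple(p for p in self.phases if p.start_s >= s0 - 1e-12 and p.end_s <= s1 + 1e-12)

    def ds_fraction_pct(self, k: int = 0) -> float:
        s0, s1 = self.strides[k]
        ds = sum(p.duration_s for p in self.phases_in_stride(k) if p.label.startswith("DS"))
        return 100.0 * ds / (s1 - s0)

    def ss_fraction_pct(self, k: int = 0) -> float:
        return 100.0 - self.ds_fraction_pct(k)

    def intervals(self, kind: str, k: int = 0) -> tuple[tuple[float, float], ...]:
        """Intervals of one kind ("SS" or "DS") within stride ``k``."""
        return tuple(
            (p.start_s, p.end_s)
            for p in self.phases_in_stride(k)
            if p.label.startswith(kind)
        )


def _crossing_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where y crosses ``level`` between i-1 and i."""
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def detect_gait_events(
    trial: GaitTrial,
    grf: Optional[Mapping[str, np.ndarray]] = None,
    threshold_N: float = 20.0,
    hysteresis_N: float = 5.0,
    foot_speed: Optional[Mapping[str, np.ndarray]] = None,
    stationary_fraction: float = 0.2,
) -> tuple[GaitEvent, ...]:
    """Detect heel-strike and toe-off events per side.

    With vertical ground-reaction-force traces (``grf``, one per side,
    aligned to the trial grid), contact starts when the force rises through
    ``threshold_N`` and ends when it falls through ``threshold_N -
    hysteresis_N``; event times are linearly interpolated at the crossing.
    Without force data, a foot-kinematics proxy is used: the foot is in
    stance while its speed is below ``stationary_fraction`` of its maximum.

    Raises if fewer than two right heel strikes are found (no complete
    stride).
    """
    events: list[GaitEvent] = []
    if grf is not None:
        channels = {side: (np.asarray(f, float), threshold_N, threshold_N - hysteresis_N)
                    for side, f in grf.items()}
    elif foot_speed is not None:
        channels = {}
        for side, s in foot_speed.items():
            s = np.asarray(s, float)
            level = stationary_fraction * float(np.max(np.abs(s)))
            # stance = slow foot: invert so "contact" is signal above level
            channels[side] = (-np.abs(s), -level, -level)
    else:
        raise ValidationError("need either GRF traces or foot-speed proxy channels")

    t = trial.t
    for side, (y, on_level, off_level) in channels.items():
        if y.shape != t.shape:
            raise ValidationError(f"{side} channel length != trial length")
        contact = y[0] > on_level
        for i in range(1, len(t)):
            if not contact and y[i] > on_level >= y[i - 1]:
                events.append(GaitEvent(_crossing_time(t, y, i, on_level), side, HEEL_STRIKE))
                contact = True
            elif contact and y[i] < off_level <= y[i - 1]:
                events.append(GaitEvent(_crossing_time(t, y, i, off_level), side, TOE_OFF))
                contact = False
    events.sort()
    n_rhs = sum(1 for e in events if e.side == "right" and e.type == HEEL_STRIKE)
    if n_rhs < 2:
        raise ValidationError("no complete stride: fewer than two right heel strikes detected")
    return tuple(events)


def segment_phases(events: Sequence[GaitEvent]) -> PhaseSegmentation:
    """Segment strides into SS/DS phases from an ordered event sequence.

    Within each right-heel-strike-to-right-heel-strike stride the expected
    order is: left toe-off, left heel strike, right toe-off.  DS1 runs from
    right heel strike to left toe-off, DS2 from left heel strike to right
    toe-off.  Out-of-order events raise a sequencing error naming the first
    violation.  A toe-off coincident with the contralateral heel strike gives
    a zero-duration (instantaneous) DS phase.
    """
    events = sorted(events)
    rhs = [e for e in events if e.side == "right" and e.type == HEEL_STRIKE]
    if len(rhs) < 2:
        raise ValidationError("no complete stride: fewer than two right heel strikes")

    strides: list[tuple[float, float]] = []
    phases: list[Phase] = []
    for a, b in zip(rhs[:-1], rhs[1:]):
        inside = [e for e in events if a.time_s < e.time_s < b.time_s or
                  (e.time_s == a.time_s and e is not a) or (e.time_s == b.time_s and e is not b)]
        def _pop(side: str, typ: str, after: float) -> GaitEvent:
            for e in inside:
                if e.side == side and e.type == typ and e.time_s >= after - 1e-12:
                    return e
            raise ValidationError(
                f"sequencing error in stride [{a.time_s:.6g}, {b.time_s:.6g}]: "
                f"expected {side} {typ} after t={after:.6g}"
            )
        lto = _pop("left", TOE_OFF, a.time_s)
        lhs = _pop("left", HEEL_STRIKE, lto.time_s)
        rto = _pop("right", TOE_OFF, lhs.time_s)
        if not (a.time_s <= lto.time_s <= lhs.time_s <= rto.time_s <= b.time_s):
            raise ValidationError(
                f"sequencing error in stride [{a.time_s:.6g}, {b.time_s:.6g}]: "
                f"events out of order at t={lto.time_s:.6g}"
            )
        strides.append((a.time_s, b.time_s))
        phases.extend([
            Phase("DS1", a.time_s, lto.time_s),
            Phase("SS_right", lto.time_s, lhs.time_s),
            Phase("DS2", lhs.time_s, rto.time_s),
            Phase("SS_left", rto.time_s, b.time_s),
        ])
    return PhaseSegmentation(strides=tuple(strides), phases=tuple(phases))


def _periodic_interp(t_out: np.ndarray, t_src: np.ndarray, y_src: np.ndarray) -> np.ndarray:
    """Interpolate a periodic signal (period = source span) at arbitrary times."""
    period = t_src[-1] - t_src[0]
    phase = np.mod(t_out - t_src[0], period) + t_src[0]
    if y_src.ndim == 1:
        return np.interp(phase, t_src, y_src, period=None)
    return np.column_stack([np.interp(phase, t_src, y_src[:, j]) for j in range(y_src.shape[1])])


def synchronize_bilateral(
    right_stride: GaitTrial,
    left_stride: GaitTrial,
    upper_body: Optional[GaitTrial] = None,
) -> GaitTrial:
    """Build one whole-body stride on the right-stride time base.

    The left stride (captured on its own left-heel-strike-to-left-heel-strike
    window) is divided at the right heel strike event it contains and
    re-ordered so that every output sample of the left-leg channels is
    synchronous with the right-leg sample, treating the left stride as one
    period of a periodic signal.  Upper-body channels, when given, are
    resampled the same way from their own window.
    """
    rhs_in_left = [e for e in left_stride.events
                   if e.side == "right" and e.type == HEEL_STRIKE]
    if not rhs_in_left:
        raise ValidationError("left stride must contain a right heel strike event")
    t_split = rhs_in_left[0].time_s
    t_out = right_stride.t

    def _resample(src: GaitTrial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # source time aligned so that t_split maps to the right-stride start
        t_query = t_split + (t_out - t_out[0])
        q = _periodic_interp(t_query, src.t, src.q)
        qd = _periodic_interp(t_query, src.t, src.qd)
        tau = _periodic_interp(t_query, src.t, src.tau)
        return q, qd, tau

    parts_q = [right_stride.q]
    parts_qd = [right_stride.qd]
    parts_tau = [right_stride.tau]
    dof_ids = list(right_stride.dof_ids)
    for src in filter(None, [left_stride, upper_body]):
        missing = set(dof_ids) & set(src.dof_ids)
        if missing:
            raise ValidationError(f"duplicate channels across segments: {sorted(missing)}")
        q, qd, tau = _resample(src)
        parts_q.append(q)
        parts_qd.append(qd)
        parts_tau.append(tau)
        dof_ids.extend(src.dof_ids)

    # left-side events remapped onto the output window through the same shift
    period = left_stride.t[-1] - left_stride.t[0]
    extra = []
    for e in left_stride.events:
        if e.side != "left":
            continue
        dt = np.mod(e.time_s - t_split, period)
        t_new = t_out[0] + dt
        if t_out[0] <= t_new <= t_out[-1]:
            extra.append(GaitEvent(float(t_new), e.side, e.type))
    events = tuple(sorted(set(right_stride.events) | set(extra)))

    return GaitTrial(
        t=t_out.copy(),
        q=np.hstack(parts_q),
        qd=np.hstack(parts_qd),
        tau=np.hstack(parts_tau),
        v=right_stride.v.copy(),
        dof_ids=tuple(dof_ids),
        events=events,
        meta={**right_stride.meta, "synchronized": True},
    )


def froude_number(
    mean_speed_mps: float,
    height_m: float,
    g: float = GRAVITY,
    leg_length_factor: float = 0.53,
) -> float:
    """Dimensionless walking speed ``Fr = v / sqrt(g l)``.

    Leg length ``l`` is estimated as ``leg_length_factor * height``
    (0.53 by convention).
    """
    if height_m <= 0:
        raise ValidationError("height must be > 0")
    if mean_speed_mps < 0:
        raise ValidationError("speed must be >= 0")
    leg = leg_length_factor * height_m
    return mean_speed_mps / np.sqrt(g * leg)


@dataclass(frozen=True)
class COTCurve:
    """Laurent-form cost-of-transport curve ``COT(v) = c_m1/v + c0 + c1*v``.

    Convex on v > 0 iff ``c_m1 > 0``; then the interior minimum (if also
    ``c1 > 0``) sits at ``v* = sqrt(c_m1/c1)``.
    """

    c_m1: float
    c0: float
    c1: float
    domain: tuple[float, float]
    residuals: np.ndarray
    convex: bool
    argmin_speed: Optional[float]

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(v, dtype=float)
        out = self.c_m1 / v + self.c0 + self.c1 * v
        return float(out) if out.ndim == 0 else out


def fit_cot_curve(points: Iterable[tuple[float, float]]) -> COTCurve:
    """Ordinary least squares fit of COT-vs-speed on the basis {1/v, 1, v}."""
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (speed, COT) pairs")
    v, y = pts[:, 0], pts[:, 1]
    if np.unique(v).size < 3:
        raise ValidationError("need at least 3 distinct speeds for the Laurent fit")
    if np.any(v <= 0):
        raise ValidationError("speeds must be positive")
    X = np.column_stack([1.0 / v, np.ones_like(v), v])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValidationError("rank-deficient design (duplicate speeds?)")
    resid = y - X @ coef
    c_m1, c0, c1 = (float(c) for c in coef)
    convex = c_m1 > 0
    argmin = float(np.sqrt(c_m1 / c1)) if (c_m1 > 0 and c1 > 0) else None
    return COTCurve(
        c_m1=c_m1, c0=c0, c1=c1,
        domain=(float(v.min()), float(v.max())),
        residuals=resid, convex=convex, argmin_speed=argmin,
    )


def _union_average(t: np.ndarray, y: np.ndarray,
                   intervals: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """(time-average over union of intervals, total duration)."""
    total_dur = 0.0
    total_int = 0.0
    for (a, b) in intervals:
        if b <= a:
            continue
        total_int += interval_average(t, y, a, b) * (b - a)
        total_dur += b - a
    if total_dur == 0:
        return np.nan, 0.0
    return total_int / total_dur, total_dur


def phase_cot(
    trace: EnergeticsTrace,
    segmentation: PhaseSegmentation,
    subject: SubjectProfile,
    stride: int = 0,
    g: float = GRAVITY,
) -> dict:
    """Total and phase-specific COT with duration and MEE shares for one stride.

    The phase-specific COT evaluates the interval form of the cost of
    transport with T the union of SS (or DS) intervals.  The %MEE shares come
    from phase integrals of ``e_met`` over the stride integral and sum to
    100%, as do the duration shares.
    """
    s0, s1 = segmentation.strides[stride]
    if s0 < trace.t[0] - 1e-9 or s1 > trace.t[-1] + 1e-9:
        raise ValidationError("segmentation stride extends beyond trace")
    out: dict = {}
    e_tot, dur_tot = _union_average(trace.t, trace.e_met, [(s0, s1)])
    v_tot, _ = _union_average(trace.t, trace.v, [(s0, s1)])
    out["COT_total"] = e_tot / (subject.mass_kg * g * v_tot)
    for kind in ("SS", "DS"):
        ivals = segmentation.intervals(kind, stride)
        e_avg, dur = _union_average(trace.t, trace.e_met, ivals)
        v_avg, _ = _union_average(trace.t, trace.v, ivals)
        out[f"COT_{kind}"] = e_avg / (subject.mass_kg * g * v_avg) if dur > 0 else np.nan
        out[f"%duration_{kind}"] = 100.0 * dur / dur_tot
        out[f"%MEE_{kind}"] = 100.0 * (e_avg * dur if dur > 0 else 0.0) / (e_tot * dur_tot)
    return out


def parameter_correlations(dataset: pd.DataFrame, response: str = "mee_W") -> pd.DataFrame:
    """Pearson correlations between subject parameters and measured MEE.

    ``dataset`` has one row per subject with the response column (measured
    mean MEE rate at preferred speed, W) and one column per parameter.
    Returns r, R^2 and the two-sided p-value per parameter; parameters with
    zero variance are flagged undefined.
    """
    if len(dataset) < 3:
        raise ValidationError("need at least 3 subjects for correlation screening")
    if response not in dataset.columns:
        raise ValidationError(f"response column {response!r} missing")
    rows = []
    y = dataset[response].to_numpy(dtype=float)
    for col in dataset.columns:
        if col == response:
            continue
        x = dataset[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"parameter": col, "r": np.nan, "r2": np.nan,
                         "p": np.nan, "undefined": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"parameter": col, "r": float(r), "r2": float(r) ** 2,
                     "p": float(p), "undefined": False})
    return pd.DataFrame(rows).set_index("parameter")
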