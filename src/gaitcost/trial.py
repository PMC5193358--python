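"""Time-gridded joint-space gait trial container.

A trial holds, on a strictly increasing uniform time grid, the joint angles
``q`` (rad), angular velocities ``qd`` (rad/s) and actuator torques ``tau``
(N*m) for each DOF, the center-of-mass speed ``v`` (m/s), the gait events,
and an optional non-negative torque-independent cocontraction heat trace
``qcc`` (W per DOF).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .subjects import ValidationError

__all__ = ["GaitEvent", "GaitTrial", "HEEL_STRIKE", "TOE_OFF"]

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single gait event: (time, side, type)."""

    time_s: float
    side: str  # {"left", "right"}
    type: str  # {"heel_strike", "toe_off"}

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"event side must be left/right, got {self.side!r}")
        if self.type not in (HEEL_STRIKE, TOE_OFF):
            raise ValidationError(f"event type must be heel_strike/toe_off, got {self.type!r}")


@dataclass
class GaitTrial:
    """Joint-space state/input time series for one trial or stride.

    All channel arrays share the first axis with ``t``; per-DOF arrays are
    shaped ``(n_samples, n_dofs)`` in the order of ``dof_ids``.
    """

    t: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    tau: np.ndarray
    v: np.ndarray
    dof_ids: tuple[str, ...]
    events: tuple[GaitEvent, ...] = ()
    qcc: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.qd = np.atleast_2d(np.asarray(self.qd, dtype=float))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        self.v = np.asarray(self.v, dtype=float)
        self.dof_ids = tuple(self.dof_ids)
        self.events = tuple(sorted(self.events))
        n, d = self.t.shape[0], len(self.dof_ids)
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("trial time grid must be strictly increasing")
        for name, arr in (("q", self.q), ("qd", self.qd), ("tau", self.tau)):
            if arr.shape != (n, d):
                raise ValidationError(f"{name} has shape {arr.shape}, expected {(n, d)}")
        if self.v.shape != (n,):
            raise ValidationError(f"v has shape {self.v.shape}, expected {(n,)}")
        if self.qcc is not None:
            self.qcc = np.atleast_2d(np.asarray(self.qcc, dtype=float))
            if self.qcc.shape != (n, d):
                raise ValidationError(f"qcc has shape {self.qcc.shape}, expected {(n, d)}")
            if np.any(self.qcc < 0):
                raise ValidationError("qcc must be non-negative everywhere (second law)")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def n_dofs(self) -> int:
        return len(self.dof_ids)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def qcc_or_zero(self) -> np.ndarray:
        if self.qcc is None:
            return np.zeros_like(self.tau)
        return self.qcc

    def time_shift(self, dt: float) -> "GaitTrial":
        """The same trial with every timestamp (and event) shifted by ``dt``."""
        events = tuple(replace(e, time_s=e.time_s + dt) for e in self.events)
        return GaitTrial(
            t=self.t + dt, q=self.q, qd=self.qd, tau=self.tau, v=self.v,
            dof_ids=self.dof_ids, events=events, qcc=self.qcc, meta=dict(self.meta),
        )
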