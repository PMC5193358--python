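"""Trial, events, and report file formats.

The native trial format is a CSV with columns ``time_s``, ``com_speed_mps``,
then per DOF ``<dof_id>_angle_rad``, ``<dof_id>_velocity_radps``,
``<dof_id>_torque_Nm`` and optionally ``<dof_id>_qcc_W``; gait events travel
in a JSON sidecar.  A tab-delimited motion dialect is also read: a header
block of ``key=value`` lines terminated by ``endheader``, then a row of
column names, then data rows; angles are converted from degrees when the
header declares ``inDegrees=yes``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .energetics import EnergeticsTrace
from .subjects import DOFCatalog, ValidationError
from .trial import GaitEvent, GaitTrial

__all__ = [
    "read_trial",
    "write_trial",
    "read_events",
    "write_events",
    "write_trace_csv",
]


def write_events(events, path: str | Path) -> None:
    payload = [{"side": e.side, "type": e.type, "time_s": e.time_s} for e in events]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_events(path: str | Path) -> tuple[GaitEvent, ...]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return tuple(sorted(
        GaitEvent(time_s=float(d["time_s"]), side=d["side"], type=d["type"])
        for d in payload
    ))


def write_trial(trial: GaitTrial, path: str | Path,
                events_path: Optional[str | Path] = None) -> None:
    """Write a trial as native CSV (and its events sidecar when asked)."""
    cols: dict[str, np.ndarray] = {
        "time_s": trial.t,
        "com_speed_mps": trial.v,
    }
    for j, dof in enumerate(trial.dof_ids):
        cols[f"{dof}_angle_rad"] = trial.q[:, j]
        cols[f"{dof}_velocity_radps"] = trial.qd[:, j]
        cols[f"{dof}_torque_Nm"] = trial.tau[:, j]
        if trial.qcc is not None:
            cols[f"{dof}_qcc_W"] = trial.qcc[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    if events_path is not None:
        write_events(trial.events, events_path)


def _read_motion_dialect(path: Path) -> tuple[pd.DataFrame, bool]:
    """Read the tab-delimited motion dialect; returns (frame, in_degrees)."""
    header: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.lower() == "endheader":
            body_start = i + 1
            break
        if "=" in s:
            k, _, v = s.partition("=")
            header[k.strip().lower()] = v.strip()
    if body_start is None:
        raise ValidationError(f"{path}: no 'endheader' line found in motion file")
    names = lines[body_start].rstrip("\n").split("\t")
    rows = []
    for ln, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        s = line.strip()
        if not s:
            continue
        parts = s.split("\t")
        if len(parts) != len(names):
            raise ValidationError(f"{path}: parse error at line {ln}: "
                                  f"expected {len(names)} columns, got {len(parts)}")
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise ValidationError(f"{path}: parse error at line {ln}: {exc}") from exc
    df = pd.DataFrame(rows, columns=names)
    in_degrees = header.get("indegrees", "no").lower() == "yes"
    return df, in_degrees


def read_trial(
    path: str | Path,
    catalog: DOFCatalog,
    events_path: Optional[str | Path] = None,
    derive_missing_velocity: bool = False,
) -> GaitTrial:
    """Read a trial file (native CSV or the motion dialect) against a catalog.

    Unknown columns are ignored; missing required columns raise a schema
    error listing them.  With ``derive_missing_velocity``, absent velocity
    columns are filled by central differences of the angles (flagged in the
    trial metadata).
    """
    path = Path(path)
    in_degrees = False
    if path.suffix.lower() in (".mot", ".sto"):
        df, in_degrees = _read_motion_dialect(path)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValidationError(f"{path}: parse error: {exc}") from exc

    time_col = "time_s" if "time_s" in df.columns else (
        "time" if "time" in df.columns else None)
    if time_col is None:
        raise ValidationError(f"{path}: missing required column time_s")
    t = df[time_col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2
        raise ValidationError(f"{path}: non-monotone time at row {bad}")

    missing: list[str] = []
    derived: list[str] = []
    n, ndof = len(t), catalog.n
    q = np.zeros((n, ndof))
    qd = np.zeros((n, ndof))
    tau = np.zeros((n, ndof))
    qcc = None
    deg = np.pi / 180.0
    for j, dof in enumerate(catalog.dof_ids):
        acol, vcol, tcol = f"{dof}_angle_rad", f"{dof}_velocity_radps", f"{dof}_torque_Nm"
        if acol not in df.columns:
            missing.append(acol)
            continue
        q[:, j] = df[acol].to_numpy(dtype=float)
        if in_degrees:
            q[:, j] *= deg
        if vcol in df.columns:
            qd[:, j] = df[vcol].to_numpy(dtype=float)
            if in_degrees:
                qd[:, j] *= deg
        elif derive_missing_velocity:
            qd[:, j] = np.gradient(q[:, j], t)
            derived.append(vcol)
        else:
            missing.append(vcol)
        if tcol in df.columns:
            tau[:, j] = df[tcol].to_numpy(dtype=float)
        else:
            missing.append(tcol)
        ccol = f"{dof}_qcc_W"
        if ccol in df.columns:
            if qcc is None:
                qcc = np.zeros((n, ndof))
            qcc[:, j] = df[ccol].to_numpy(dtype=float)
    if missing:
        raise ValidationError(f"{path}: missing required columns: {missing}")

    vcol = "com_speed_mps" if "com_speed_mps" in df.columns else None
    if vcol is None:
        raise ValidationError(f"{path}: missing required column com_speed_mps")
    v = df[vcol].to_numpy(dtype=float)

    events = read_events(events_path) if events_path is not None else ()
    meta = {"source": str(path)}
    if derived:
        meta["derived_velocity_columns"] = derived
    return GaitTrial(t=t, q=q, qd=qd, tau=tau, v=v, dof_ids=catalog.dof_ids,
                     events=events, qcc=qcc, meta=meta)


def write_trace_csv(trace: EnergeticsTrace, path: str | Path,
                    icot_values: Optional[np.ndarray] = None,
                    per_dof: bool = True) -> None:
    """Write an energetics trace as CSV, one row per sample."""
    cols = {
        "time_s": trace.t,
        "work_rate_W": trace.work_rate,
        "q_am_W": trace.q_am,
        "q_sl_W": trace.q_sl,
        "q_cc_W": trace.q_cc,
        "bmr_W": np.full_like(trace.t, trace.bmr_W),
        "e_met_W": trace.e_met,
    }
    if icot_values is not None:
        cols["icot"] = icot_values
    if per_dof:
        for j, dof in enumerate(trace.dof_ids):
            cols[f"{dof}_e_met_W"] = trace.per_dof_e_met[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
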