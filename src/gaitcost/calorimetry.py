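"""Indirect-calorimetry processing.

Converts per-minute respiratory gas exchange (VO2, VCO2 in L/min) to a
metabolic rate in watts, and reduces rest / per-speed minute records to a
basal metabolic rate and a representative steady-state MEE.  The gas-exchange
conversion is valid while the respiratory exchange ratio (RER = VCO2/VO2)
stays below unity, i.e. while metabolism is predominantly aerobic; records
violating that carry a warning flag rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .subjects import ValidationError

__all__ = [
    "MetabolicRecord",
    "RERWarning",
    "vo2_to_watts",
    "compute_bmr",
    "representative_mee",
    "read_metabolic_csv",
]

#: Brockway gas-exchange energy equivalents, kJ per liter (urinary nitrogen
#: term dropped: not measured in a gas-only protocol).
BROCKWAY_O2_KJ_PER_L = 16.58
BROCKWAY_CO2_KJ_PER_L = 4.51
#: Fixed oxygen energy equivalent, kJ per liter O2.
DEFAULT_O2_EQUIVALENT_KJ_PER_L = 20.1

KJ_PER_MIN_TO_W = 1000.0 / 60.0


class RERWarning(UserWarning):
    """Respiratory exchange ratio >= 1: conversion validity violated."""


@dataclass(frozen=True)
class MetabolicRecord:
    """Per-minute gas exchange for one condition (rest or one speed)."""

    condition: str
    vo2_L_min: tuple[float, ...]
    vco2_L_min: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vo2_L_min", tuple(float(x) for x in self.vo2_L_min))
        object.__setattr__(self, "vco2_L_min", tuple(float(x) for x in self.vco2_L_min))
        if len(self.vo2_L_min) != len(self.vco2_L_min):
            raise ValidationError("vo2 and vco2 must have the same number of minutes")
        if any(x < 0 for x in self.vo2_L_min + self.vco2_L_min):
            raise ValidationError("gas volumes must be non-negative")

    @property
    def duration_min(self) -> int:
        return len(self.vo2_L_min)

    def rer(self) -> np.ndarray:
        vo2 = np.asarray(self.vo2_L_min)
        vco2 = np.asarray(self.vco2_L_min)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(vo2 > 0, vco2 / vo2, np.nan)


def vo2_to_watts(
    vo2_L_min: float,
    vco2_L_min: float = 0.0,
    method: str = "brockway",
    o2_equivalent_kJ_per_L: float = DEFAULT_O2_EQUIVALENT_KJ_PER_L,
    warn_on_rer: bool = True,
) -> float:
    """Convert per-minute gas exchange to watts.

    ``brockway``: (16.58*VO2 + 4.51*VCO2) kJ/min.  ``fixed_equivalent``:
    VO2 times a fixed energy equivalent (default 20.1 kJ/L O2).  Emits an
    :class:`RERWarning` when RER >= 1, where the aerobic conversion is no
    longer valid.
    """
    if vo2_L_min < 0 or vco2_L_min < 0:
        raise ValidationError("gas volumes must be non-negative")
    if warn_on_rer and vo2_L_min > 0 and vco2_L_min / vo2_L_min >= 1.0:
        warnings.warn(
            f"RER = {vco2_L_min / vo2_L_min:.3f} >= 1: gas-exchange conversion "
            "assumes predominantly aerobic metabolism",
            RERWarning,
            stacklevel=2,
        )
    if method == "brockway":
        kj_min = BROCKWAY_O2_KJ_PER_L * vo2_L_min + BROCKWAY_CO2_KJ_PER_L * vco2_L_min
    elif method == "fixed_equivalent":
        kj_min = o2_equivalent_kJ_per_L * vo2_L_min
    else:
        raise ValidationError(f"unknown conversion method {method!r}")
    return kj_min * KJ_PER_MIN_TO_W


def _tail_mean_watts(record: MetabolicRecord, n_required: int, n_tail: int,
                     method: str, strict: bool) -> float:
    if strict and record.duration_min != n_required:
        raise ValidationError(
            f"insufficient data: need exactly {n_required} minutes for condition "
            f"{record.condition!r}, got {record.duration_min}"
        )
    if record.duration_min < n_required:
        raise ValidationError(
            f"insufficient data: need at least {n_required} minutes for condition "
            f"{record.condition!r}, got {record.duration_min}"
        )
    watts = [
        vo2_to_watts(o2, co2, method=method)
        for o2, co2 in zip(record.vo2_L_min, record.vco2_L_min)
    ]
    return float(np.mean(watts[-n_tail:]))


def compute_bmr(record: MetabolicRecord, method: str = "brockway") -> float:
    """Basal metabolic rate (W): mean of the last three of >= 6 rest minutes."""
    return _tail_mean_watts(record, n_required=6, n_tail=3, method=method, strict=False)


def representative_mee(record: MetabolicRecord, method: str = "brockway",
                       strict: bool = True) -> float:
    """Representative MEE (W) for one speed: mean of the last 3 of 5 minutes.

    With ``strict`` (default) the record must hold exactly five per-minute
    measurements, matching the five-minute treadmill bouts of the protocol.
    """
    return _tail_mean_watts(record, n_required=5, n_tail=3, method=method, strict=strict)


def read_metabolic_csv(path) -> dict[str, MetabolicRecord]:
    """Read a metabolic CSV (columns minute, condition, vo2_L_min, vco2_L_min)."""
    df = pd.read_csv(path)
    required = {"minute", "condition", "vo2_L_min", "vco2_L_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metabolic file missing columns: {sorted(missing)}")
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("minute")
        out[str(cond)] = MetabolicRecord(
            condition=str(cond),
            vo2_L_min=tuple(grp["vo2_L_min"].astype(float)),
            vco2_L_min=tuple(grp["vco2_L_min"].astype(float)),
        )
    return out
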