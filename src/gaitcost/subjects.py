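"""Subject and degree-of-freedom (DOF) parameterization.

The metabolic model is subject-specific: each subject is described by the
energetic parameters that correlate with whole-body metabolic rate during
walking -- body mass ``M`` (kg), height ``H`` (m), age ``A`` (years, a proxy
for aerobic capacity), maximum isometric knee extension torque (N*m, measured
at 60 deg flexion), and sitting basal metabolic rate (W).

Each joint DOF carries a reference maximum torque for an average adult.  A
subject's maximum torque at DOF ``i`` is obtained by linearly scaling the
measured knee torque with the ratio of reference torques, so the single
dynamometer measurement propagates a subject-specific strength scale to the
whole body.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

__all__ = [
    "SubjectProfile",
    "DOF",
    "DOFCatalog",
    "NormalizedParameters",
    "ValidationError",
    "normalize_parameters",
    "scaled_max_torque",
    "default_catalog",
    "load_subject",
    "save_subject",
    "load_catalog",
]

#: Normalization scales: "maximum order of magnitude" of each subject
#: parameter.  Mass, age and torques are divided by 100; height by 10.
MASS_SCALE = 100.0
AGE_SCALE = 100.0
TORQUE_SCALE = 100.0
HEIGHT_SCALE = 10.0


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-specific energetic parameters.

    Parameters
    ----------
    id : str
        Subject label.
    sex : {"M", "F"}
        Selects the sex-specific reference-torque catalog by default.
    mass_kg, height_m, age_yr : float
        Anthropometrics; all strictly positive.
    knee_max_torque_Nm : float
        Maximum isometric knee extension torque (right knee, 60 deg flexion).
    bmr_W : float
        Sitting basal metabolic rate in watts.
    vo2max_W : float, optional
        Maximum aerobic power in watts; enables the upper-bound constraint on
        average metabolic rate when known.
    """

    id: str
    sex: str
    mass_kg: float
    height_m: float
    age_yr: float
    knee_max_torque_Nm: float
    bmr_W: float
    vo2max_W: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("mass_kg", "height_m", "age_yr", "knee_max_torque_Nm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.bmr_W < 0:
            raise ValidationError(f"bmr_W must be >= 0, got {self.bmr_W!r}")
        if self.vo2max_W is not None and self.vo2max_W <= 0:
            raise ValidationError(f"vo2max_W must be > 0 when given, got {self.vo2max_W!r}")


@dataclass(frozen=True)
class DOF:
    """One revolute joint degree of freedom."""

    dof_id: str
    name: str
    side: str  # {"left", "right", "central"}
    reference_max_torque_Nm: float
    mirror_of: Optional[str] = None


@dataclass(frozen=True)
class DOFCatalog:
    """Ordered catalog of DOFs with reference maximum torques.

    ``reference_knee_torque_Nm`` is the average-adult knee value that anchors
    the strength scaling; the subject's measured knee torque divided by it is
    the dimensionless subject-strength ratio.
    """

    dofs: tuple[DOF, ...]
    reference_knee_torque_Nm: float
    label: str = "catalog"

    def __post_init__(self) -> None:
        if len(self.dofs) < 1:
            raise ValidationError("catalog must contain at least one DOF")
        if not self.reference_knee_torque_Nm > 0:
            raise ValidationError("reference_knee_torque_Nm must be > 0")
        ids = [d.dof_id for d in self.dofs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dof_id in catalog")
        by_id = {d.dof_id: d for d in self.dofs}
        for d in self.dofs:
            if not d.reference_max_torque_Nm > 0:
                raise ValidationError(f"reference torque of {d.dof_id} must be > 0")
            if d.mirror_of is not None:
                other = by_id.get(d.mirror_of)
                if other is None:
                    raise ValidationError(f"{d.dof_id}: mirror_of {d.mirror_of!r} not in catalog")
                if other.reference_max_torque_Nm != d.reference_max_torque_Nm:
                    raise ValidationError(
                        f"mirror pair ({d.dof_id}, {d.mirror_of}) has unequal reference torques"
                    )

    @property
    def n(self) -> int:
        return len(self.dofs)

    @property
    def dof_ids(self) -> tuple[str, ...]:
        return tuple(d.dof_id for d in self.dofs)

    def index(self, dof_id: str) -> int:
        for i, d in enumerate(self.dofs):
            if d.dof_id == dof_id:
                return i
        raise KeyError(f"unknown dof_id {dof_id!r}")

    def __getitem__(self, dof_id: str) -> DOF:
        return self.dofs[self.index(dof_id)]


@dataclass(frozen=True)
class NormalizedParameters:
    """Dimensionless subject and DOF parameters.

    ``m_n = M/100``, ``a_n = A/100``, ``h_n = H/10`` and per-DOF
    ``tau_n[i] = reference torque / 100``.  ``strength_ratio`` is the raw
    (already dimensionless) knee ratio used in the DOF-specific factor.
    """

    m_n: float
    a_n: float
    h_n: float
    tau_n: tuple[float, ...]
    strength_ratio: float
    scales: dict = field(
        default_factory=lambda: {
            "mass": MASS_SCALE,
            "age": AGE_SCALE,
            "height": HEIGHT_SCALE,
            "torque": TORQUE_SCALE,
        }
    )

    def denormalize(self) -> dict:
        """Recover the dimensional inputs (inverse of :func:`normalize_parameters`)."""
        return {
            "mass_kg": self.m_n * self.scales["mass"],
            "age_yr": self.a_n * self.scales["age"],
            "height_m": self.h_n * self.scales["height"],
            "reference_torques_Nm": tuple(t * self.scales["torque"] for t in self.tau_n),
        }


def normalize_parameters(subject: SubjectProfile, catalog: DOFCatalog) -> NormalizedParameters:
    """Normalize subject parameters by their maximum orders of magnitude.

    Mass, age, and all maximum joint torques are divided by 100; height by 10.
    The knee strength ratio is kept raw, being dimensionless already.
    """
    return NormalizedParameters(
        m_n=subject.mass_kg / MASS_SCALE,
        a_n=subject.age_yr / AGE_SCALE,
        h_n=subject.height_m / HEIGHT_SCALE,
        tau_n=tuple(d.reference_max_torque_Nm / TORQUE_SCALE for d in catalog.dofs),
        strength_ratio=subject.knee_max_torque_Nm / catalog.reference_knee_torque_Nm,
    )


def scaled_max_torque(subject: SubjectProfile, catalog: DOFCatalog, dof_id: str) -> float:
    """Subject-specific maximum torque at one DOF.

    ``tau_i_max = (tau_knee_max / tau_ref_knee) * tau_ref_i`` -- the measured
    knee torque linearly scaled by the catalog's torque ratio.  Homogeneous of
    degree 1 in the measured knee torque, and equal for mirrored DOFs.
    """
    dof = catalog[dof_id]  # raises KeyError on unknown id
    ratio = subject.knee_max_torque_Nm / catalog.reference_knee_torque_Nm
    return ratio * dof.reference_max_torque_Nm


# ---------------------------------------------------------------------------
# Default 42-DOF catalogs and file I/O


def _load_packaged(name: str) -> dict:
    with resources.files("gaitcost.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _catalog_from_dict(payload: dict) -> DOFCatalog:
    dofs = tuple(
        DOF(
            dof_id=row["dof_id"],
            name=row["name"],
            side=row["side"],
            reference_max_torque_Nm=float(row["reference_max_torque_Nm"]),
            mirror_of=row.get("mirror_of"),
        )
        for row in payload["dofs"]
    )
    return DOFCatalog(
        dofs=dofs,
        reference_knee_torque_Nm=float(payload["reference_knee_torque_Nm"]),
        label=payload.get("label", "catalog"),
    )


def default_catalog(sex: str = "M") -> DOFCatalog:
    """The packaged 42-DOF whole-body catalog for the given sex.

    Three rotational DOFs for each of two ankles, knees, hips, wrists,
    elbows and shoulders, plus a 3-DOF neck and waist.  Only the male
    sagittal hip (240.1 N*m) and ankle (151.5 N*m) entries come from
    measured reference data; other entries are catalog defaults from the
    strength literature and are flagged as such in the file.
    """
    if sex not in ("M", "F"):
        raise ValidationError(f"sex must be 'M' or 'F', got {sex!r}")
    name = "catalog_male.json" if sex == "M" else "catalog_female.json"
    return _catalog_from_dict(_load_packaged(name))


def load_catalog(path: str | Path) -> DOFCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        return _catalog_from_dict(json.load(fh))


def load_subject(path: str | Path) -> SubjectProfile:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    return SubjectProfile(
        id=str(d["id"]),
        sex=d["sex"],
        mass_kg=float(d["mass_kg"]),
        height_m=float(d["height_m"]),
        age_yr=float(d["age_yr"]),
        knee_max_torque_Nm=float(d["knee_max_torque_Nm"]),
        bmr_W=float(d["bmr_W"]),
        vo2max_W=float(d["vo2max_W"]) if d.get("vo2max_W") is not None else None,
    )


def save_subject(subject: SubjectProfile, path: str | Path) -> None:
    payload = {
        "id": subject.id,
        "sex": subject.sex,
        "mass_kg": subject.mass_kg,
        "height_m": subject.height_m,
        "age_yr": subject.age_yr,
        "knee_max_torque_Nm": subject.knee_max_torque_Nm,
        "bmr_W": subject.bmr_W,
        "vo2max_W": subject.vo2max_W,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
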