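"""Patient records, clinical discretization, and AHI severity classes.

The apnea–hypopnea index (AHI, events per hour of sleep) places every
patient into one of four ordered severity classes: ``norm`` (AHI < 5),
``mild`` (5 ≤ AHI < 15), ``mod`` (15 ≤ AHI < 30), ``sev`` (AHI ≥ 30).
Six clinical measurements are discretized into the parameter classes
used for risk compatibility between patients: gender, age group,
hypertension, obesity, thick neck, and daytime sleepiness.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Severity(enum.IntEnum):
    """Ordered OSA severity classes; the integer order is the clinical order."""

    norm = 0
    mild = 1
    mod = 2
    sev = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: class boundaries (right-open): norm < 5 <= mild < 15 <= mod < 30 <= sev
SEVERITY_BOUNDS = (5.0, 15.0, 30.0)


def classify_ahi_severity(ahi: float) -> Severity:
    """Map an AHI value (events/h) to its severity class.

    Raises
    ------
    ValueError
        If *ahi* is negative or not finite.
    """
    if not math.isfinite(ahi) or ahi < 0:
        raise ValueError(f"AHI must be a non-negative finite number, got {ahi!r}")
    if ahi < SEVERITY_BOUNDS[0]:
        return Severity.norm
    if ahi < SEVERITY_BOUNDS[1]:
        return Severity.mild
    if ahi < SEVERITY_BOUNDS[2]:
        return Severity.mod
    return Severity.sev


@dataclass(frozen=True)
class DiscretizationRules:
    """Cutoffs for the six-parameter discretization.

    The strictness of each comparison follows standard clinical usage:
    hypertension is systolic > 140 or diastolic > 90 mmHg; obesity is
    BMI > 30 kg/m²; thick neck is NC ≥ 40 cm for women and ≥ 43 cm for
    men; sleepiness is ESS ≥ 11. Age groups are half-open intervals
    closed on the right: (-inf, 20], (20, 40], (40, 60], (60, inf).
    """

    systolic_hbp: float = 140.0  # strictly greater
    diastolic_hbp: float = 90.0  # strictly greater
    bmi_obese: float = 30.0  # strictly greater
    nc_thick_female: float = 40.0  # greater or equal
    nc_thick_male: float = 43.0  # greater or equal
    ess_sleepy: int = 11  # greater or equal
    age_bounds: tuple[float, ...] = (20.0, 40.0, 60.0)

    def age_group(self, age: float) -> int:
        g = 0
        for bound in self.age_bounds:
            if age > bound:
                g += 1
        return g


DEFAULT_RULES = DiscretizationRules()


@dataclass(frozen=True)
class PatientRecord:
    """Raw clinical measurements for one subject.

    Either both blood-pressure values or an explicit hypertension flag
    must be present; when ``hbp_flag`` is set it overrides the raw BP
    values during discretization.
    """

    id: str
    gender: str  # "male" | "female"
    age: float  # years
    bmi: float  # kg/m^2
    neck_circumference: float  # cm
    ess: int  # Epworth sleepiness score, 0..24
    ahi_before: float  # events/h
    systolic_bp: Optional[float] = None  # mmHg
    diastolic_bp: Optional[float] = None  # mmHg
    hbp_flag: Optional[bool] = None
    ahi_after: Optional[float] = None  # events/h
    osa_label: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.neck_circumference <= 0:
            raise ValueError("neck_circumference must be positive")
        if not (0 <= int(self.ess) <= 24):
            raise ValueError(f"ess must lie in [0, 24], got {self.ess}")
        if self.ahi_before < 0:
            raise ValueError("ahi_before must be non-negative")
        if self.ahi_after is not None and self.ahi_after < 0:
            raise ValueError("ahi_after must be non-negative")
        has_bp = self.systolic_bp is not None and self.diastolic_bp is not None
        if not has_bp and self.hbp_flag is None:
            raise ValueError(
                "record needs either both blood-pressure values or an hbp_flag"
            )


@dataclass(frozen=True)
class ClassProfile:
    """The six discretized parameter classes of one patient.

    ``thick_neck`` and its complement thin neck are a single Boolean
    slot; the remaining slots are gender, age group, hypertension,
    obesity, and sleepiness.
    """

    gender_class: str  # "M" | "F"
    age_group: int  # 0..3
    hbp: bool
    obese: bool
    thick_neck: bool
    sleepiness: bool

    def __post_init__(self) -> None:
        if self.gender_class not in ("M", "F"):
            raise ValueError("gender_class must be 'M' or 'F'")
        if not (0 <= self.age_group <= 3):
            raise ValueError("age_group must lie in 0..3")

    @property
    def thin_neck(self) -> bool:
        return not self.thick_neck

    def as_tuple(self) -> tuple:
        """The six class slots in canonical order, for slot-wise comparison."""
        return (
            self.gender_class,
            self.age_group,
            self.hbp,
            self.obese,
            self.thick_neck,
            self.sleepiness,
        )


#: canonical slot names, aligned with :meth:`ClassProfile.as_tuple`
PROFILE_SLOTS = ("gender", "age_group", "hbp", "obese", "thick_neck", "sleepiness")


def discretize_patient(
    record: PatientRecord, rules: DiscretizationRules = DEFAULT_RULES
) -> ClassProfile:
    """Discretize one record into its six parameter classes.

    ``hbp_flag`` overrides raw BP values when present. Raises
    ``ValueError`` when neither BP values nor a flag are available
    (unreachable for records built through :class:`PatientRecord`).
    """
    if record.hbp_flag is not None:
        hbp = bool(record.hbp_flag)
    elif record.systolic_bp is not None and record.diastolic_bp is not None:
        hbp = (
            record.systolic_bp > rules.systolic_hbp
            or record.diastolic_bp > rules.diastolic_hbp
        )
    else:  # pragma: no cover - guarded by PatientRecord invariants
        raise ValueError(f"record {record.id}: no blood-pressure information")

    if record.gender == "female":
        thick = record.neck_circumference >= rules.nc_thick_female
        gender_class = "F"
    else:
        thick = record.neck_circumference >= rules.nc_thick_male
        gender_class = "M"

    return ClassProfile(
        gender_class=gender_class,
        age_group=rules.age_group(record.age),
        hbp=hbp,
        obese=record.bmi > rules.bmi_obese,
        thick_neck=thick,
        sleepiness=int(record.ess) >= rules.ess_sleepy,
    )


def prevalence_percent(count: int, total: int, ndigits: int = 2) -> float:
    """Prevalence as a percentage of *total*, rounded to *ndigits* places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)
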