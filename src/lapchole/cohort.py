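"""Patient data model, the preoperative risk score, and the intraoperative
difficulty grade.

The preoperative scale is an additive point system over eight routinely
available variables (age, sex, ASA class, primary diagnosis, gallbladder wall
thickness, common bile duct diameter, prior ERCP, admission type) with a total
of 0-19 points, stratified into low (0-1), intermediate (2-6) and high (7-19)
risk of a difficult laparoscopic cholecystectomy.

The reference standard is a four-grade intraoperative difficulty scale based
on the state of the gallbladder, the cystic pedicle and adhesions; grades 1-2
are classed as easy procedures and 3-4 as difficult ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from typing import Callable, Iterable, Optional, Union

import pandas as pd

__all__ = [
    "Sex",
    "Diagnosis",
    "Admission",
    "RiskCategory",
    "Difficulty",
    "OutcomeFlags",
    "PatientRecord",
    "ScoreBreakdown",
    "IntraoperativeFindings",
    "ValidationError",
    "MissingDataError",
    "RangeError",
    "SCORED_FIELDS",
    "OUTCOME_FIELDS",
    "EXCLUSION_REASONS",
    "preoperative_score",
    "risk_category",
    "grade_from_findings",
    "dichotomize_difficulty",
    "apply_eligibility_filter",
    "score_frame",
]


class ValidationError(ValueError):
    """A field value is outside its allowed domain."""


class MissingDataError(ValidationError):
    """A scored variable needed by the preoperative scale is absent."""


class RangeError(ValidationError):
    """A numeric argument is outside its documented range."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Diagnosis(str, Enum):
    PANCREATITIS = "pancreatitis"
    BILIARY_COLIC = "biliary_colic"
    CHOLEDOCHOLITHIASIS = "choledocholithiasis"
    CHOLECYSTITIS = "cholecystitis"


class Admission(str, Enum):
    ELECTIVE = "elective"
    DELAYED = "delayed"
    EMERGENCY = "emergency"


class RiskCategory(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class Difficulty(str, Enum):
    EASY = "easy"
    DIFFICULT = "difficult"


#: Variables the preoperative scale needs; a record missing any of them is
#: ineligible (the study excluded such patients rather than imputing).
SCORED_FIELDS = (
    "age",
    "sex",
    "asa",
    "diagnosis",
    "wall_thickness_mm",
    "cbd_diameter_mm",
    "preop_ercp",
    "admission",
)

OUTCOME_FIELDS = (
    "conversion",
    "subtotal",
    "cvs_failed",
    "bleeding",
    "bile_leak",
    "cbd_injury",
)

#: Fixed precedence of the eligibility-filter reasons; a record is tallied
#: under the first reason that applies.
EXCLUSION_REASONS = ("planned_open", "missing_variables", "malignancy")


def _coerce_enum(value, enum_cls, name: str):
    if value is None or isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        raise ValidationError(
            f"{name}={value!r} is not one of {[e.value for e in enum_cls]}"
        ) from None


@dataclass
class OutcomeFlags:
    """Surgical outcomes recorded for one procedure (independent flags)."""

    conversion: bool = False
    subtotal: bool = False
    cvs_failed: bool = False
    bleeding: bool = False
    bile_leak: bool = False
    cbd_injury: bool = False


@dataclass
class PatientRecord:
    """One patient's preoperative variables plus, when available, the
    intraoperative difficulty grade and surgical outcomes.

    Scored variables may be ``None`` (missing in the chart); such records are
    rejected by :func:`preoperative_score` and removed by the eligibility
    filter.
    """

    id: str
    age: Optional[int] = None
    sex: Optional[Sex] = None
    asa: Optional[int] = None
    diagnosis: Optional[Diagnosis] = None
    wall_thickness_mm: Optional[float] = None
    cbd_diameter_mm: Optional[float] = None
    preop_ercp: Optional[bool] = None
    admission: Optional[Admission] = None
    planned_open: bool = False
    malignancy: bool = False
    intraop_grade: Optional[int] = None
    outcomes: Optional[OutcomeFlags] = None

    def __post_init__(self):
        self.sex = _coerce_enum(self.sex, Sex, "sex")
        self.diagnosis = _coerce_enum(self.diagnosis, Diagnosis, "diagnosis")
        self.admission = _coerce_enum(self.admission, Admission, "admission")
        if self.age is not None and self.age < 18:
            raise ValidationError(f"age must be >= 18, got {self.age}")
        if self.asa is not None and self.asa not in (1, 2, 3, 4, 5):
            raise ValidationError(f"asa must be in 1..5, got {self.asa}")
        for attr in ("wall_thickness_mm", "cbd_diameter_mm"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValidationError(f"{attr} must be >= 0, got {v}")
        if self.intraop_grade is not None and self.intraop_grade not in (1, 2, 3, 4):
            raise ValidationError(
                f"intraop_grade must be in 1..4, got {self.intraop_grade}"
            )

    def missing_scored_fields(self) -> list[str]:
        return [f for f in SCORED_FIELDS if getattr(self, f) is None]


@dataclass
class ScoreBreakdown:
    """Per-variable points, the 0-19 total, and the risk stratum."""

    points_age: int
    points_sex: int
    points_asa: int
    points_diagnosis: int
    points_wall: int
    points_cbd: int
    points_ercp: int
    points_admission: int
    total: int = field(init=False)
    category: RiskCategory = field(init=False)

    def __post_init__(self):
        self.total = (
            self.points_age
            + self.points_sex
            + self.points_asa
            + self.points_diagnosis
            + self.points_wall
            + self.points_cbd
            + self.points_ercp
            + self.points_admission
        )
        self.category = risk_category(self.total)


@dataclass
class IntraoperativeFindings:
    """Ordinal level (1-4) of each intraoperative descriptor."""

    gallbladder: int
    cystic_pedicle: int
    adhesions: int

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v not in (1, 2, 3, 4):
                raise ValidationError(f"{f.name} must be in 1..4, got {v!r}")


# --- point tables ---------------------------------------------------------

# ASA 5 is scored as the ASA 4 row: the point table stops at ASA 4 while the
# cohort description uses a joint "4-5" stratum; mapping 5 upward preserves
# monotonicity of the score in physical status.
_ASA_POINTS = {1: 0, 2: 1, 3: 2, 4: 7, 5: 7}
_DIAGNOSIS_POINTS = {
    Diagnosis.PANCREATITIS: 0,
    Diagnosis.BILIARY_COLIC: 0,
    Diagnosis.CHOLEDOCHOLITHIASIS: 1,
    Diagnosis.CHOLECYSTITIS: 4,
}
_ADMISSION_POINTS = {Admission.ELECTIVE: 0, Admission.DELAYED: 1, Admission.EMERGENCY: 2}

#: Boundary semantics: age exactly 40 scores 1 ("40+"); wall exactly 3 mm
#: scores 2 (">= 3 mm"); CBD exactly 6 mm scores 0 (the table prints "> 6 mm").
AGE_CUTOFF = 40
WALL_CUTOFF_MM = 3.0
CBD_CUTOFF_MM = 6.0


def preoperative_score(record: PatientRecord) -> ScoreBreakdown:
    """Compute the additive preoperative difficulty score for one patient.

    Raises
    ------
    MissingDataError
        If any of the eight scored variables is absent (the record is
        ineligible; no imputation is attempted).
    """
    missing = record.missing_scored_fields()
    if missing:
        raise MissingDataError(
            f"record {record.id!r} is missing scored variables: {missing}"
        )
    return ScoreBreakdown(
        points_age=1 if record.age >= AGE_CUTOFF else 0,
        points_sex=1 if record.sex is Sex.MALE else 0,
        points_asa=_ASA_POINTS[record.asa],
        points_diagnosis=_DIAGNOSIS_POINTS[record.diagnosis],
        points_wall=2 if record.wall_thickness_mm >= WALL_CUTOFF_MM else 0,
        points_cbd=1 if record.cbd_diameter_mm > CBD_CUTOFF_MM else 0,
        points_ercp=1 if record.preop_ercp else 0,
        points_admission=_ADMISSION_POINTS[record.admission],
    )


def risk_category(total: int) -> RiskCategory:
    """Map a total score to its risk stratum: 0-1 low, 2-6 intermediate,
    7-19 high (boundaries inclusive)."""
    if not 0 <= total <= 19:
        raise RangeError(f"total score must be in 0..19, got {total}")
    if total <= 1:
        return RiskCategory.LOW
    if total <= 6:
        return RiskCategory.INTERMEDIATE
    return RiskCategory.HIGH


def grade_from_findings(
    findings: IntraoperativeFindings,
    strategy: Union[str, Callable[[int, int, int], int]] = "max",
) -> int:
    """Aggregate the three descriptor levels into one overall grade.

    The default ``"max"`` strategy makes any grade-4 feature (e.g. a
    completely obscured gallbladder) grade the whole case 4; the source scale
    states no combination rule, so the aggregation is configurable via a
    callable taking the three levels.
    """
    levels = (findings.gallbladder, findings.cystic_pedicle, findings.adhesions)
    if callable(strategy):
        grade = strategy(*levels)
        if grade not in (1, 2, 3, 4):
            raise ValidationError(f"strategy returned invalid grade {grade!r}")
        return grade
    if strategy == "max":
        return max(levels)
    raise ValidationError(f"unknown aggregation strategy {strategy!r}")


def dichotomize_difficulty(grade: int) -> Difficulty:
    """Grades 1-2 are easy, 3-4 difficult."""
    if grade in (1, 2):
        return Difficulty.EASY
    if grade in (3, 4):
        return Difficulty.DIFFICULT
    raise ValidationError(f"grade must be in 1..4, got {grade!r}")


def apply_eligibility_filter(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], Counter]:
    """Drop ineligible records: planned open cholecystectomy, missing scored
    variables, gallbladder malignancy.

    Reasons are checked in that fixed order and each excluded record is
    tallied under the first matching reason only, so
    ``len(included) + sum(tally.values()) == len(records)``.
    """
    included: list[PatientRecord] = []
    tally: Counter = Counter({r: 0 for r in EXCLUSION_REASONS})
    for rec in records:
        if rec.planned_open:
            tally["planned_open"] += 1
        elif rec.missing_scored_fields():
            tally["missing_variables"] += 1
        elif rec.malignancy:
            tally["malignancy"] += 1
        else:
            included.append(rec)
    return included, tally


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a cohort table.

    Expects the scored-variable columns of the cohort CSV schema; returns a
    copy with ``score_total`` and ``risk_category`` columns appended.
    Rows with a missing scored variable get NaN / NA in both columns — the
    columnar counterpart of :class:`MissingDataError`.
    """
    out = df.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    wall = pd.to_numeric(out["wall_thickness_mm"], errors="coerce")
    cbd = pd.to_numeric(out["cbd_diameter_mm"], errors="coerce")
    asa = pd.to_numeric(out["asa"], errors="coerce")
    ercp = pd.to_numeric(out["preop_ercp"], errors="coerce")

    pts = (
        (age >= AGE_CUTOFF).astype(float)
        + out["sex"].map({"female": 0.0, "male": 1.0})
        + asa.map({k: float(v) for k, v in _ASA_POINTS.items()})
        + out["diagnosis"].map({d.value: float(p) for d, p in _DIAGNOSIS_POINTS.items()})
        + (wall >= WALL_CUTOFF_MM) * 2.0
        + (cbd > CBD_CUTOFF_MM) * 1.0
        + (ercp > 0).astype(float)
        + out["admission"].map({a.value: float(p) for a, p in _ADMISSION_POINTS.items()})
    )
    # any NaN input propagates to a NaN total
    for col, vals in (("age", age), ("wall_thickness_mm", wall),
                      ("cbd_diameter_mm", cbd), ("asa", asa), ("preop_ercp", ercp)):
        pts = pts.where(~vals.isna())
    out["score_total"] = pts
    cat = pd.Series(pd.NA, index=out.index, dtype="object")
    cat[pts <= 1] = RiskCategory.LOW.value
    cat[(pts >= 2) & (pts <= 6)] = RiskCategory.INTERMEDIATE.value
    cat[pts >= 7] = RiskCategory.HIGH.value
    cat[pts.isna()] = pd.NA
    out["risk_category"] = cat
    return out
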