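"""Domain types for a perinatal dating cohort.

A :class:`PregnancyRecord` carries every dating source observed for one
singleton pregnancy — the self-reported last menstrual period (LMP) with its
certainty flag, zero or more ultrasound exams (each with the clinician's GA
estimate at the exam, in days), and the Capurro neonatal-exam GA — together
with the birth date, birth weight, infant sex, and the maternal covariates
used for stratified analyses.

GA is integer days throughout; completed weeks are ``days // 7``.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Maximum plausible clinician GA at an ultrasound exam (45 weeks).
MAX_GA_AT_EXAM_DAYS = 315


class Method(str, Enum):
    """A GA-at-birth estimation method (dating source)."""

    US_7_20 = "us_7_20"
    US_21_28 = "us_21_28"
    US_29P = "us_29p"
    LMP = "lmp"
    CAPURRO = "capurro"


class Window(str, Enum):
    """Gestational window of an ultrasound exam, by GA at the exam."""

    US_7_20 = "us_7_20"
    US_21_28 = "us_21_28"
    US_29P = "us_29p"
    OUT_OF_RANGE = "out_of_range"

    @property
    def method(self) -> Method:
        if self is Window.OUT_OF_RANGE:
            raise ValueError("out-of-range window has no method label")
        return Method(self.value)


class MaturityClass(str, Enum):
    """Birth maturity: preterm (<37 w), term (37-41 w), postterm (>=42 w)."""

    PRETERM = "preterm"
    TERM = "term"
    POSTTERM = "postterm"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: Covariate categories used by the stratified difference tables.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "city": ("city_1", "city_2"),
    "age_group": ("10-19", "20-34", ">=35"),
    "ethnicity": ("white", "mixed", "black"),
    "schooling": ("<=4", "5-8", ">=9"),
    "marital": ("married", "not_married"),
    "parity": ("1", "2-3", ">=4"),
}


class UltrasoundExam(BaseModel):
    """One ultrasound exam: its date and the clinician GA at the exam."""

    model_config = ConfigDict(frozen=True)

    exam_date: dt.date
    ga_at_exam_days: int = Field(ge=0, le=MAX_GA_AT_EXAM_DAYS)


class PregnancyRecord(BaseModel):
    """One pregnancy with all dating sources and covariates.

    Invariants enforced at construction: ``birth_date`` present, every exam
    date on or before the birth date, positive birth weight. An LMP *after*
    the birth date is representable (it is a real data error the pipeline
    must handle), and is rejected downstream by :func:`gestage.dating.ga_from_lmp`.
    """

    id: str
    birth_date: dt.date
    birth_weight_g: float = Field(gt=0)
    infant_sex: Sex
    lmp_date: dt.date | None = None
    lmp_certain: bool | None = None
    us_exams: list[UltrasoundExam] = Field(default_factory=list)
    capurro_ga_days: int | None = Field(default=None, ge=0)
    covariates: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _exams_before_birth(self) -> "PregnancyRecord":
        for exam in self.us_exams:
            if exam.exam_date > self.birth_date:
                raise ValueError(
                    f"record {self.id}: ultrasound exam on {exam.exam_date} "
                    f"is after birth on {self.birth_date}"
                )
        return self


class GAEstimate(BaseModel):
    """A (method, GA at birth) pair; weeks are completed weeks."""

    model_config = ConfigDict(frozen=True)

    method: Method
    ga_at_birth_days: int = Field(ge=0)

    @property
    def ga_at_birth_weeks(self) -> int:
        return self.ga_at_birth_days // 7
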