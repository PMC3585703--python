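"""Per-method GA-at-birth estimation and maturity classification.

Dating formulas
---------------
* LMP:  GA at birth = birth date − LMP date (exact calendar day count).
* Ultrasound:  GA at birth = (birth date − exam date) + clinician GA at exam.
* Capurro:  the recorded neonatal-exam value is used verbatim.

Ultrasound exams are grouped by the GA at the exam into three windows using
completed-week semantics: 7-20 weeks = [49, 146] days, 21-28 weeks =
[147, 202] days, 29+ weeks = >= 203 days; exams before 7 weeks fall outside
every window. Within a window the earliest exam is used.

Maturity cut-offs follow the completed-week convention: preterm < 259 days
(<37 w), postterm >= 294 days (>=42 w).
"""

from __future__ import annotations

import datetime as dt
import logging

from gestage.errors import DomainError, InvalidIntervalError, MissingSourceError
from gestage.records import (
    GAEstimate,
    MaturityClass,
    Method,
    PregnancyRecord,
    UltrasoundExam,
    Window,
)

logger = logging.getLogger(__name__)

PRETERM_CUTOFF_DAYS = 37 * 7  # 259: first term day
POSTTERM_CUTOFF_DAYS = 42 * 7  # 294: first postterm day

#: Inclusive day bounds of the two closed ultrasound windows.
WINDOW_BOUNDS = {
    Window.US_7_20: (49, 146),
    Window.US_21_28: (147, 202),
}
US_29P_START = 203


def ga_from_lmp(lmp_date: dt.date | None, birth_date: dt.date) -> int:
    """GA at birth in days from the last menstrual period.

    Raises
    ------
    MissingSourceError
        if ``lmp_date`` is absent.
    InvalidIntervalError
        if the LMP lies after the birth date.
    """
    if lmp_date is None:
        raise MissingSourceError("LMP date is absent")
    if lmp_date > birth_date:
        raise InvalidIntervalError(
            f"LMP {lmp_date} is after birth date {birth_date}"
        )
    return (birth_date - lmp_date).days


def ga_from_us(exam: UltrasoundExam, birth_date: dt.date) -> int:
    """GA at birth in days from one ultrasound exam.

    Days elapsed between exam and birth are added to the clinician's GA
    estimate at the exam.
    """
    if exam.exam_date > birth_date:
        raise InvalidIntervalError(
            f"ultrasound exam {exam.exam_date} is after birth date {birth_date}"
        )
    return (birth_date - exam.exam_date).days + exam.ga_at_exam_days


def window_of(exam: UltrasoundExam) -> Window:
    """Gestational window of an exam by its GA at the exam (days)."""
    ga = exam.ga_at_exam_days
    if ga < WINDOW_BOUNDS[Window.US_7_20][0]:
        return Window.OUT_OF_RANGE
    if ga <= WINDOW_BOUNDS[Window.US_7_20][1]:
        return Window.US_7_20
    if ga <= WINDOW_BOUNDS[Window.US_21_28][1]:
        return Window.US_21_28
    return Window.US_29P


def earliest_in_window(
    exams: list[UltrasoundExam], window: Window
) -> UltrasoundExam | None:
    """The exam in ``window`` with the smallest GA at exam, or ``None``.

    Ties on GA at exam are broken by input order (first wins), so the
    selection is deterministic for any exam list.
    """
    best: UltrasoundExam | None = None
    for exam in exams:
        if window_of(exam) is not window:
            continue
        if best is None or exam.ga_at_exam_days < best.ga_at_exam_days:
            best = exam
    return best


def classify_maturity(ga_at_birth_days: int) -> MaturityClass:
    """Preterm / term / postterm from GA at birth in days."""
    if ga_at_birth_days < 0:
        raise DomainError(f"negative GA at birth: {ga_at_birth_days}")
    if ga_at_birth_days < PRETERM_CUTOFF_DAYS:
        return MaturityClass.PRETERM
    if ga_at_birth_days >= POSTTERM_CUTOFF_DAYS:
        return MaturityClass.POSTTERM
    return MaturityClass.TERM


def gather_estimates(
    record: PregnancyRecord,
) -> tuple[dict[Method, GAEstimate], set[Method]]:
    """All per-method GA estimates for one record.

    Returns the estimates keyed by method plus the set of methods whose
    source is present but yields an invalid interval (logged and omitted).
    At most one estimate per method: each ultrasound window contributes its
    earliest exam, the LMP and Capurro at most one value each.
    """
    estimates: dict[Method, GAEstimate] = {}
    invalid: set[Method] = set()

    for window in (Window.US_7_20, Window.US_21_28, Window.US_29P):
        exam = earliest_in_window(record.us_exams, window)
        if exam is None:
            continue
        # record invariant guarantees exam_date <= birth_date
        estimates[window.method] = GAEstimate(
            method=window.method,
            ga_at_birth_days=ga_from_us(exam, record.birth_date),
        )

    if record.lmp_date is not None:
        try:
            days = ga_from_lmp(record.lmp_date, record.birth_date)
        except InvalidIntervalError:
            logger.warning(
                "record %s: LMP %s after birth %s; LMP estimate dropped",
                record.id,
                record.lmp_date,
                record.birth_date,
            )
            invalid.add(Method.LMP)
        else:
            estimates[Method.LMP] = GAEstimate(
                method=Method.LMP, ga_at_birth_days=days
            )

    if record.capurro_ga_days is not None:
        estimates[Method.CAPURRO] = GAEstimate(
            method=Method.CAPURRO, ga_at_birth_days=record.capurro_ga_days
        )

    return estimates, invalid


def all_estimates(record: PregnancyRecord) -> list[GAEstimate]:
    """One GAEstimate per available source, in method order.

    Sources with invalid intervals (LMP after birth) are omitted and logged.
    An empty list is a valid outcome for a record with no usable source.
    """
    estimates, _ = gather_estimates(record)
    return [estimates[m] for m in Method if m in estimates]
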