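import datetime as dt

import pytest

from gestage.growth import default_reference
from gestage.records import PregnancyRecord, Sex, UltrasoundExam
from gestage.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def growth_ref():
    return default_reference()


@pytest.fixture(scope="session")
def noiseless_cohort(growth_ref):
    """Zero-error cohort: every source available, every estimate exact."""
    cfg = SimulationConfig.noiseless(n=600, seed=7)
    records, truth = generate(cfg, growth_ref=growth_ref)
    return records, truth


@pytest.fixture(scope="session")
def default_cohort(growth_ref):
    """Default-condition cohort at the study's sample size."""
    cfg = SimulationConfig.default(n=1483, seed=11)
    records, truth = generate(cfg, growth_ref=growth_ref)
    return records, truth


def make_record(
    rid: str = "r1",
    birth: dt.date = dt.date(2008, 10, 7),
    weight: float = 3300.0,
    sex: Sex = Sex.MALE,
    **kwargs,
) -> PregnancyRecord:
    return PregnancyRecord(
        id=rid, birth_date=birth, birth_weight_g=weight, infant_sex=sex, **kwargs
    )


def us_exam(birth: dt.date, true_ga_at_birth: int, ga_at_exam: int) -> UltrasoundExam:
    """Exam scheduled so that its implied GA at birth equals ``true_ga_at_birth``."""
    return UltrasoundExam(
        exam_date=birth - dt.timedelta(days=true_ga_at_birth - ga_at_exam),
        ga_at_exam_days=ga_at_exam,
    )
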