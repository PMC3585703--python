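"""Date arithmetic, window grouping and maturity classification."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestage.dating import (
    all_estimates,
    classify_maturity,
    earliest_in_window,
    ga_from_lmp,
    ga_from_us,
    window_of,
)
from gestage.errors import DomainError, InvalidIntervalError, MissingSourceError
from gestage.records import MaturityClass, Method, UltrasoundExam, Window

from conftest import make_record, us_exam

D = dt.date


class TestGAFromLMP:
    @pytest.mark.parametrize(
        "lmp, birth, expected",
        [
            (D(2008, 10, 7), D(2008, 10, 7), 0),
            (D(2008, 1, 1), D(2008, 10, 7), 280),  # spans the 2008 leap day
            (D(2007, 12, 25), D(2008, 10, 1), 281),
        ],
    )
    def test_exact_day_count(self, lmp, birth, expected):
        assert ga_from_lmp(lmp, birth) == expected

    def test_lmp_after_birth_is_invalid(self):
        with pytest.raises(InvalidIntervalError):
            ga_from_lmp(D(2008, 10, 8), D(2008, 10, 7))

    def test_absent_lmp_signals_missing_source(self):
        with pytest.raises(MissingSourceError):
            ga_from_lmp(None, D(2008, 10, 7))

    @given(
        start=st.dates(min_value=D(1999, 1, 1), max_value=D(2011, 12, 31)),
        span=st.integers(min_value=0, max_value=320),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_numpy_datetime64_oracle(self, start, span):
        birth = start + dt.timedelta(days=span)
        oracle = (np.datetime64(birth) - np.datetime64(start)).astype(int)
        assert ga_from_lmp(start, birth) == int(oracle)


class TestGAFromUS:
    def test_exam_on_birth_date(self):
        exam = UltrasoundExam(exam_date=D(2008, 9, 22), ga_at_exam_days=266)
        assert ga_from_us(exam, D(2008, 9, 22)) == 266

    def test_elapsed_days_plus_exam_ga(self):
        # 196 elapsed calendar days + 84 at exam
        exam = UltrasoundExam(exam_date=D(2008, 3, 10), ga_at_exam_days=84)
        assert ga_from_us(exam, D(2008, 9, 22)) == 280

    def test_exam_after_birth_is_invalid(self):
        exam = UltrasoundExam(exam_date=D(2008, 9, 23), ga_at_exam_days=84)
        with pytest.raises(InvalidIntervalError):
            ga_from_us(exam, D(2008, 9, 22))

    @given(
        exam_date=st.dates(min_value=D(2007, 1, 1), max_value=D(2008, 12, 31)),
        elapsed=st.integers(min_value=0, max_value=250),
        ga_at_exam=st.integers(min_value=0, max_value=315),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_calendar_oracle(self, exam_date, elapsed, ga_at_exam):
        birth = exam_date + dt.timedelta(days=elapsed)
        exam = UltrasoundExam(exam_date=exam_date, ga_at_exam_days=ga_at_exam)
        oracle = (np.datetime64(birth) - np.datetime64(exam_date)).astype(int)
        assert ga_from_us(exam, birth) == int(oracle) + ga_at_exam


class TestWindows:
    @pytest.mark.parametrize(
        "ga_days, window",
        [
            (49, Window.US_7_20),
            (146, Window.US_7_20),
            (147, Window.US_21_28),
            (202, Window.US_21_28),
            (203, Window.US_29P),
            (310, Window.US_29P),
            (48, Window.OUT_OF_RANGE),
            (0, Window.OUT_OF_RANGE),
        ],
    )
    def test_completed_week_boundaries(self, ga_days, window):
        exam = UltrasoundExam(exam_date=D(2008, 1, 1), ga_at_exam_days=ga_days)
        assert window_of(exam) is window

    def test_windows_partition_the_day_range(self):
        for ga in range(49, 316):
            exam = UltrasoundExam(exam_date=D(2008, 1, 1), ga_at_exam_days=ga)
            assert window_of(exam) in (
                Window.US_7_20,
                Window.US_21_28,
                Window.US_29P,
            )

    def test_earliest_exam_wins_within_window(self):
        at_22w = UltrasoundExam(exam_date=D(2008, 5, 1), ga_at_exam_days=154)
        at_27w = UltrasoundExam(exam_date=D(2008, 6, 5), ga_at_exam_days=189)
        assert earliest_in_window([at_27w, at_22w], Window.US_21_28) is at_22w

    def test_empty_or_absent_window(self):
        assert earliest_in_window([], Window.US_7_20) is None
        late = UltrasoundExam(exam_date=D(2008, 6, 5), ga_at_exam_days=210)
        assert earliest_in_window([late], Window.US_7_20) is None

    def test_tie_broken_by_record_order(self):
        a = UltrasoundExam(exam_date=D(2008, 5, 1), ga_at_exam_days=154)
        b = UltrasoundExam(exam_date=D(2008, 5, 2), ga_at_exam_days=154)
        assert earliest_in_window([a, b], Window.US_21_28) is a
        assert earliest_in_window([b, a], Window.US_21_28) is b


class TestMaturity:
    @pytest.mark.parametrize(
        "days, cls",
        [
            (258, MaturityClass.PRETERM),
            (259, MaturityClass.TERM),
            (293, MaturityClass.TERM),
            (294, MaturityClass.POSTTERM),
            (0, MaturityClass.PRETERM),
        ],
    )
    def test_cutoffs(self, days, cls):
        assert classify_maturity(days) is cls

    def test_negative_ga_is_domain_error(self):
        with pytest.raises(DomainError):
            classify_maturity(-1)

    def test_monotone_in_ga(self):
        order = {MaturityClass.PRETERM: 0, MaturityClass.TERM: 1, MaturityClass.POSTTERM: 2}
        ranks = [order[classify_maturity(d)] for d in range(0, 330)]
        assert ranks == sorted(ranks)


class TestAllEstimates:
    def test_lmp_only(self):
        r = make_record(lmp_date=D(2008, 1, 1))
        ests = all_estimates(r)
        assert [e.method for e in ests] == [Method.LMP]
        assert ests[0].ga_at_birth_days == 280
        assert ests[0].ga_at_birth_weeks == 40

    def test_two_windows_plus_lmp(self):
        birth = D(2008, 10, 7)
        r = make_record(
            lmp_date=D(2008, 1, 1),
            us_exams=[us_exam(birth, 280, 84), us_exam(birth, 280, 168)],
        )
        methods = {e.method for e in all_estimates(r)}
        assert methods == {Method.US_7_20, Method.US_21_28, Method.LMP}
        assert all(e.ga_at_birth_days == 280 for e in all_estimates(r))

    def test_no_sources_gives_empty_list(self):
        assert all_estimates(make_record()) == []

    def test_invalid_lmp_omitted(self):
        r = make_record(birth=D(2008, 10, 7), lmp_date=D(2008, 10, 8))
        assert all_estimates(r) == []

    def test_never_two_estimates_with_same_method(self, default_cohort):
        records, _ = default_cohort
        for r in records[:300]:
            methods = [e.method for e in all_estimates(r)]
            assert len(methods) == len(set(methods))
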