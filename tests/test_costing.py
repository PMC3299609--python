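"""Bottom-up costing, productivity valuation and annualization."""

from dataclasses import replace
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shouldercoi import (
    GradePolicy,
    InputError,
    PatientRecord,
    ProductivityParameters,
    Provider,
    Sex,
    UnitCostSchedule,
    ValuationMethod,
    VisitEvent,
    Window,
    annualize,
    cost_patient,
    daily_productivity_cost,
    estimate_secondary_costs,
    sick_leave_day_equivalents,
    value_sick_leave,
)
from shouldercoi.cohort import ImagingEvent, Modality, SickLeavePrescription
from shouldercoi.costing import COST_COMPONENTS
from shouldercoi.errors import ConfigurationError

WINDOW = Window(date(2009, 1, 1), date(2009, 6, 30))
SCHEDULE = UnitCostSchedule()
PARAMS = ProductivityParameters()


def _record(**kwargs) -> PatientRecord:
    base = dict(patient_id="p1", age=40, sex=Sex.MALE, municipality="municipality_a")
    base.update(kwargs)
    return PatientRecord(**base)


def _sl(start_day: int, n_days: int, grade: int = 100) -> SickLeavePrescription:
    from datetime import timedelta

    start = WINDOW.start + timedelta(days=start_day)
    return SickLeavePrescription(start, start + timedelta(days=n_days - 1), grade)


class TestDailyProductivityCost:
    def test_printed_formula(self):
        # income + 40% social fares + 28% indirect taxes
        assert daily_productivity_cost(100.0, PARAMS) == pytest.approx(168.0)

    def test_zero_income(self):
        assert daily_productivity_cost(0.0, PARAMS) == 0.0

    def test_inverse_of_daily_price(self):
        # EUR 205/day corresponds to a mean daily income of 205/1.68
        assert daily_productivity_cost(122.02, PARAMS) == pytest.approx(205.0, abs=0.1)

    def test_negative_income_rejected(self):
        with pytest.raises(InputError):
            daily_productivity_cost(-1.0, PARAMS)


class TestSickLeaveDayEquivalents:
    def test_full_grade_counts_calendar_days(self):
        assert sick_leave_day_equivalents([_sl(0, 10)], WINDOW) == 10.0

    def test_graded_weighting_halves_grade_50(self):
        assert sick_leave_day_equivalents([_sl(0, 10, grade=50)], WINDOW) == 5.0

    def test_full_day_policy_ignores_grades(self):
        rx = [_sl(0, 10, 100), _sl(20, 10, 50)]
        assert sick_leave_day_equivalents(rx, WINDOW, GradePolicy.FULL_DAY) == 20.0

    def test_overlap_takes_max_grade(self):
        # days 0-9 at 50%, days 5-9 also at 100%: 5*0.5 + 5*1.0
        rx = [_sl(0, 10, 50), _sl(5, 5, 100)]
        assert sick_leave_day_equivalents(rx, WINDOW) == 7.5

    def test_clipped_to_window(self):
        rx = [_sl(WINDOW.n_days - 5, 30)]  # runs past the window end
        assert sick_leave_day_equivalents(rx, WINDOW) == 5.0

    def test_extending_window_never_decreases(self):
        rx = [_sl(170, 30)]
        wide = Window(WINDOW.start, date(2009, 12, 31))
        assert sick_leave_day_equivalents(rx, wide) >= sick_leave_day_equivalents(rx, WINDOW)


class TestValueSickLeave:
    def test_human_capital(self):
        assert value_sick_leave(10, SCHEDULE, PARAMS) == pytest.approx(2050.0)

    def test_friction_scales_by_factor(self):
        friction = replace(PARAMS, valuation_method=ValuationMethod.FRICTION)
        assert value_sick_leave(10, SCHEDULE, friction) == pytest.approx(793.35)

    @pytest.mark.parametrize("method", list(ValuationMethod))
    def test_zero_days(self, method):
        assert value_sick_leave(0, SCHEDULE, replace(PARAMS, valuation_method=method)) == 0.0


class TestCostPatient:
    def test_gp_and_pt_visits(self):
        rec = _record(
            visits=[
                VisitEvent(date(2009, 2, 1), Provider.GP, ("M751",)),
                VisitEvent(date(2009, 2, 8), Provider.PT, ("M751",)),
                VisitEvent(date(2009, 2, 15), Provider.PT, ("M751",)),
            ]
        )
        s = cost_patient(rec, WINDOW)
        assert s.healthcare_total == pytest.approx(207.0)
        assert s.total == pytest.approx(207.0)

    def test_empty_utilization_all_zero(self):
        s = cost_patient(_record(), WINDOW)
        assert s.total == 0.0
        assert all(getattr(s, c) == 0.0 for c in COST_COMPONENTS)

    def test_imaging_only(self):
        rec = _record(
            imaging=[
                ImagingEvent(date(2009, 3, 1), Modality.XRAY),
                ImagingEvent(date(2009, 3, 2), Modality.ULTRASOUND),
            ]
        )
        assert cost_patient(rec, WINDOW).healthcare_total == pytest.approx(189.0)

    def test_totals_satisfy_invariants(self):
        rec = _record(
            visits=[VisitEvent(date(2009, 2, 1), Provider.GP, ("M751",))],
            sick_leaves=[_sl(30, 14)],
        )
        s = cost_patient(rec, WINDOW)
        assert s.total == pytest.approx(s.healthcare_total + s.sick_leave)
        assert s.sick_leave == pytest.approx(14 * 205.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        field=st.sampled_from(
            ["gp_visit", "pt_visit", "xray", "ultrasound", "medicine_per_prescription", "sick_leave_day"]
        ),
        factor=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_linearity_in_each_unit_cost(self, field, factor):
        """Scaling one unit price scales exactly that component, nothing else."""
        rec = _record(
            visits=[
                VisitEvent(date(2009, 2, 1), Provider.GP, ("M751",)),
                VisitEvent(date(2009, 2, 8), Provider.PT, ("M751",)),
            ],
            imaging=[ImagingEvent(date(2009, 3, 1), Modality.XRAY)],
            sick_leaves=[_sl(30, 7)],
        )
        base = cost_patient(rec, WINDOW, SCHEDULE)
        scaled = cost_patient(rec, WINDOW, SCHEDULE.with_multipliers({field: factor - 1.0}))
        from shouldercoi.sensitivity import UNIT_COST_TO_COMPONENT

        target = UNIT_COST_TO_COMPONENT[field]
        for comp in COST_COMPONENTS:
            expected = getattr(base, comp) * (factor if comp == target else 1.0)
            assert getattr(scaled, comp) == pytest.approx(expected, rel=1e-12)


class TestSecondaryCosts:
    def test_published_utilization(self):
        assert estimate_secondary_costs(29, 10, 4) == 22475.0

    def test_zero(self):
        assert estimate_secondary_costs(0, 0, 0) == 0.0

    def test_one_of_each(self):
        assert estimate_secondary_costs(1, 1, 1) == 3063.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            estimate_secondary_costs(-1, 0, 0)


class TestAnnualize:
    @pytest.mark.parametrize(
        "six_month,annual", [(2069.4, 4138.8), (0.0, 0.0), (326.22, 652.44)]
    )
    def test_doubles(self, six_month, annual):
        assert annualize(six_month) == pytest.approx(annual)


def test_negative_unit_cost_rejected():
    with pytest.raises(ConfigurationError):
        UnitCostSchedule(gp_visit=-1.0)


def test_friction_factor_bounds():
    with pytest.raises(ConfigurationError):
        ProductivityParameters(friction_factor=0.0)
    with pytest.raises(ConfigurationError):
        ProductivityParameters(friction_factor=1.5)
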