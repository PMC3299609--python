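"""Bottom-up direct costing and productivity-loss valuation.

Direct healthcare costs value each recorded resource-use event (GP and PT
visits, shoulder x-ray and ultrasound, filled prescriptions) with a unit
price from the schedule.  Indirect costs value sick leave prescribed in
primary care.  Under the human-capital approach a lost working day is worth
the regional mean income loaded with social fares and indirect taxes
(here carried as a fixed daily price, EUR 205); the friction-cost method
counts only the period until a replacement worker is productive,
operationalized as a fixed fraction (0.387) of the human-capital value.

All amounts are kept at full floating precision; rounding to whole euros
happens only when reports are rendered.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping, Sequence

from .cohort import (
    Modality,
    PatientRecord,
    SickLeavePrescription,
    Window,
)
from .errors import ConfigurationError, InputError

__all__ = [
    "UnitCostSchedule",
    "ProductivityParameters",
    "ValuationMethod",
    "GradePolicy",
    "PatientCostSummary",
    "HEALTHCARE_COMPONENTS",
    "COST_COMPONENTS",
    "daily_productivity_cost",
    "sick_leave_day_equivalents",
    "value_sick_leave",
    "cost_patient",
    "cost_cohort",
    "estimate_secondary_costs",
    "annualize",
    "round_half_up",
]

#: Per-patient cost components, in report (table) order.
HEALTHCARE_COMPONENTS = ("gp", "pt", "xray", "ultrasound", "medicine")
COST_COMPONENTS = HEALTHCARE_COMPONENTS + ("sick_leave",)


class ValuationMethod(str, enum.Enum):
    HUMAN_CAPITAL = "human_capital"
    FRICTION = "friction"


class GradePolicy(str, enum.Enum):
    """How partially graded sick leave is converted to day equivalents.

    ``GRADED_WEIGHTING`` weights each calendar day by grade/100; ``FULL_DAY``
    counts every prescribed day as a full day regardless of grade.
    """

    GRADED_WEIGHTING = "graded_weighting"
    FULL_DAY = "full_day"


@dataclass(frozen=True)
class UnitCostSchedule:
    """Unit prices (EUR, 2009 price level) for the costed resource items.

    ``medicine_per_prescription`` is a cohort-average price per filled
    prescription; the study priced drugs individually from the hospital
    pharmacy list, which is not public, so the default is the cohort total
    divided by the number of prescriptions (718/58).
    """

    gp_visit: float = 107.0
    pt_visit: float = 50.0
    xray: float = 65.0
    ultrasound: float = 124.0
    medicine_per_prescription: float = 718.0 / 58.0
    orthopaedic_visit: float = 335.0
    mri: float = 308.0
    surgery_ambulatory: float = 2420.0
    sick_leave_day: float = 205.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"unit cost '{f.name}' must be >= 0")

    def with_multipliers(self, multipliers: Mapping[str, float]) -> "UnitCostSchedule":
        """Return a schedule with each named unit cost scaled by (1 + multiplier)."""
        valid = {f.name for f in fields(self)}
        changes = {}
        for name, mult in multipliers.items():
            if name not in valid:
                raise ConfigurationError(f"unknown unit-cost name '{name}'")
            if mult <= -1:
                raise ConfigurationError(f"multiplier for '{name}' must be > -1")
            changes[name] = getattr(self, name) * (1.0 + mult)
        return replace(self, **changes)


@dataclass(frozen=True)
class ProductivityParameters:
    """Wage loadings and valuation method for productivity losses.

    A day of lost production is worth the mean income plus social fares
    (default 40% of the wage) plus indirect taxes (default 28%); the
    friction factor (default 0.387) rescales human-capital totals to the
    friction-cost method.
    """

    social_fares_rate: float = 0.40
    indirect_tax_rate: float = 0.28
    friction_factor: float = 0.387
    valuation_method: ValuationMethod = ValuationMethod.HUMAN_CAPITAL

    def __post_init__(self) -> None:
        if self.social_fares_rate < 0:
            raise ConfigurationError("social_fares_rate must be >= 0")
        if self.indirect_tax_rate < 0:
            raise ConfigurationError("indirect_tax_rate must be >= 0")
        if not 0 < self.friction_factor <= 1:
            raise ConfigurationError("friction_factor must be in (0, 1]")


@dataclass(frozen=True)
class PatientCostSummary:
    """Per-patient component costs (EUR over the measurement window)."""

    patient_id: str
    gp: float = 0.0
    pt: float = 0.0
    xray: float = 0.0
    ultrasound: float = 0.0
    medicine: float = 0.0
    sick_leave: float = 0.0
    sick_leave_day_equivalents: float = 0.0

    def __post_init__(self) -> None:
        for name in COST_COMPONENTS:
            if getattr(self, name) < 0:
                raise InputError(f"negative cost component '{name}'")

    @property
    def healthcare_total(self) -> float:
        return self.gp + self.pt + self.xray + self.ultrasound + self.medicine

    @property
    def total(self) -> float:
        return self.healthcare_total + self.sick_leave

    def component(self, name: str) -> float:
        if name == "healthcare_total":
            return self.healthcare_total
        if name == "total":
            return self.total
        if name not in COST_COMPONENTS:
            raise InputError(f"unknown cost component '{name}'")
        return getattr(self, name)


def daily_productivity_cost(mean_daily_income: float, params: ProductivityParameters) -> float:
    """Value one lost working day from the mean daily income.

    Productivity loss = income + social fares + indirect taxes, i.e.
    income x (1 + social_fares_rate + indirect_tax_rate).
    """
    if mean_daily_income < 0:
        raise InputError("mean_daily_income must be >= 0")
    return mean_daily_income * (1.0 + params.social_fares_rate + params.indirect_tax_rate)


def sick_leave_day_equivalents(
    prescriptions: Iterable[SickLeavePrescription],
    window: Window,
    grade_policy: GradePolicy = GradePolicy.GRADED_WEIGHTING,
) -> float:
    """Full-day equivalents of prescribed sick leave inside the window.

    Each prescription's calendar days are clipped to the window; days are
    weighted by grade/100 under GRADED_WEIGHTING and counted as whole days
    under FULL_DAY.  Where prescriptions for the same patient overlap, the
    overlap days take the maximum grade rather than double-counting.
    """
    # Max grade per calendar day, day-level resolution (windows are months,
    # not years, so this stays cheap).
    grade_by_day: dict[int, int] = {}
    for rx in prescriptions:
        start = max(rx.start, window.start)
        end = min(rx.end, window.end)
        if end < start:
            continue
        d0 = (start - window.start).days
        for d in range(d0, d0 + (end - start).days + 1):
            if rx.grade > grade_by_day.get(d, 0):
                grade_by_day[d] = rx.grade
    if grade_policy is GradePolicy.FULL_DAY:
        return float(len(grade_by_day))
    return sum(grade_by_day.values()) / 100.0


def value_sick_leave(
    day_equivalents: float,
    schedule: UnitCostSchedule,
    params: ProductivityParameters,
) -> float:
    """Monetary value of sick leave under the configured valuation method."""
    if day_equivalents < 0:
        raise InputError("day_equivalents must be >= 0")
    cost = day_equivalents * schedule.sick_leave_day
    if params.valuation_method is ValuationMethod.FRICTION:
        cost *= params.friction_factor
    return cost


def cost_patient(
    record: PatientRecord,
    window: Window,
    schedule: UnitCostSchedule | None = None,
    params: ProductivityParameters | None = None,
    grade_policy: GradePolicy = GradePolicy.GRADED_WEIGHTING,
) -> PatientCostSummary:
    """Bottom-up costing of one patient: unit counts times unit prices."""
    schedule = schedule or UnitCostSchedule()
    params = params or ProductivityParameters()
    days = sick_leave_day_equivalents(record.sick_leaves, window, grade_policy)
    return PatientCostSummary(
        patient_id=record.patient_id,
        gp=record.n_gp_visits * schedule.gp_visit,
        pt=record.n_pt_visits * schedule.pt_visit,
        xray=record.n_imaging(Modality.XRAY) * schedule.xray,
        ultrasound=record.n_imaging(Modality.ULTRASOUND) * schedule.ultrasound,
        medicine=len(record.prescriptions) * schedule.medicine_per_prescription,
        sick_leave=value_sick_leave(days, schedule, params),
        sick_leave_day_equivalents=days,
    )


def cost_cohort(
    records: Sequence[PatientRecord],
    window: Window,
    schedule: UnitCostSchedule | None = None,
    params: ProductivityParameters | None = None,
    grade_policy: GradePolicy = GradePolicy.GRADED_WEIGHTING,
) -> list[PatientCostSummary]:
    return [cost_patient(r, window, schedule, params, grade_policy) for r in records]


def estimate_secondary_costs(
    n_referrals: int,
    n_mri: int,
    n_surgeries: int,
    schedule: UnitCostSchedule | None = None,
) -> float:
    """Estimated secondary-care cost: orthopaedic visits + MRI + ambulatory surgery."""
    if min(n_referrals, n_mri, n_surgeries) < 0:
        raise InputError("secondary-care counts must be >= 0")
    schedule = schedule or UnitCostSchedule()
    return (
        n_referrals * schedule.orthopaedic_visit
        + n_mri * schedule.mri
        + n_surgeries * schedule.surgery_ambulatory
    )


def annualize(six_month_cost: float) -> float:
    """Scale a six-month cost to an annual figure (x 2)."""
    if six_month_cost < 0:
        raise InputError("six_month_cost must be >= 0")
    return 2.0 * six_month_cost


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, matching how the report tables are printed."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)
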