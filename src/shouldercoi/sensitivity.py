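"""Deterministic one-way and multi-way sensitivity analysis.

Because the costing model values fixed utilization frequencies with unit
prices, every cost component is exactly linear in its unit price.  A
scenario therefore rescales component costs by (1 + multiplier) for every
patient, leaving frequencies untouched, and the percent change in the
total obeys a closed form:

    pct_change_total = sum_c multiplier_c * (base total of c / base grand total) * 100

Multi-way scenarios superpose.  Switching the sick-leave valuation from the
human-capital to the friction-cost method multiplies the sick-leave
component by the friction factor and leaves healthcare costs unchanged.

Perturbed confidence intervals need the patient-level distribution of the
perturbed totals; when only cohort margins are supplied they are reported
as unavailable rather than approximated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .analytics import ci95
from .costing import (
    COST_COMPONENTS,
    PatientCostSummary,
    ProductivityParameters,
    ValuationMethod,
)
from .errors import ConfigurationError, InputError
from .margins import CohortMargins

__all__ = [
    "UNIT_COST_TO_COMPONENT",
    "SensitivityScenario",
    "SensitivityResult",
    "perturb_summaries",
    "run_scenario",
    "run_method_switch",
    "scenario_table",
    "table6_scenarios",
]

#: Map from unit-cost names (as in UnitCostSchedule) to cost components.
UNIT_COST_TO_COMPONENT: dict[str, str] = {
    "gp_visit": "gp",
    "pt_visit": "pt",
    "xray": "xray",
    "ultrasound": "ultrasound",
    "medicine_per_prescription": "medicine",
    "sick_leave_day": "sick_leave",
}

CohortBase = Union[CohortMargins, Sequence[PatientCostSummary]]


@dataclass(frozen=True)
class SensitivityScenario:
    """A set of relative unit-cost changes and/or a valuation-method switch.

    ``multipliers`` maps unit-cost names to relative changes (+0.30 means
    +30%).  An empty scenario is the identity (base case).
    """

    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)
    method_override: ValuationMethod | None = None

    def __post_init__(self) -> None:
        for key, mult in self.multipliers.items():
            if key not in UNIT_COST_TO_COMPONENT:
                raise ConfigurationError(
                    f"scenario '{self.name}': unknown unit-cost name '{key}' "
                    f"(expected one of {sorted(UNIT_COST_TO_COMPONENT)})"
                )
            if mult <= -1:
                raise ConfigurationError(
                    f"scenario '{self.name}': multiplier for '{key}' must be > -1"
                )

    def component_factors(self, params: ProductivityParameters) -> dict[str, float]:
        """Per-component cost scaling factors implied by this scenario."""
        factors = {c: 1.0 for c in COST_COMPONENTS}
        for key, mult in self.multipliers.items():
            factors[UNIT_COST_TO_COMPONENT[key]] *= 1.0 + mult
        if self.method_override is ValuationMethod.FRICTION:
            factors["sick_leave"] *= params.friction_factor
        return factors


@dataclass(frozen=True)
class SensitivityResult:
    """Outcome of one scenario: percent changes and recomputed means."""

    name: str
    pct_change_total: float
    pct_change_healthcare: float
    pct_change_sick_leave: float
    new_total_mean: float
    new_healthcare_mean: float
    ci95_total: tuple[float, float] | None
    ci95_healthcare: tuple[float, float] | None


def perturb_summaries(
    summaries: Sequence[PatientCostSummary], factors: Mapping[str, float]
) -> list[PatientCostSummary]:
    """Scale each patient's component costs; utilization stays fixed."""
    out = []
    for s in summaries:
        out.append(
            replace(s, **{c: getattr(s, c) * factors.get(c, 1.0) for c in COST_COMPONENTS})
        )
    return out


def _cohort_stats(base: CohortBase) -> tuple[int, dict[str, float], dict[str, float | None]]:
    """(n, grand totals, per-patient SD of healthcare_total/total/sick_leave)."""
    rows = COST_COMPONENTS + ("healthcare_total", "total")
    if isinstance(base, CohortMargins):
        totals = {r: base.total_cost(r) for r in rows}
        sds = {r: base.sd(r) for r in ("healthcare_total", "total")}
        return base.n, totals, sds
    summaries = list(base)
    if not summaries:
        raise InputError("empty cohort")
    n = len(summaries)
    totals = {r: float(sum(s.component(r) for s in summaries)) for r in rows}
    sds = {}
    for r in ("healthcare_total", "total"):
        vals = np.array([s.component(r) for s in summaries])
        sds[r] = float(vals.std(ddof=1)) if n > 1 else None
    return n, totals, sds


def run_scenario(
    base: CohortBase,
    scenario: SensitivityScenario,
    params: ProductivityParameters | None = None,
) -> SensitivityResult:
    """Apply one scenario and recompute cohort cost summaries.

    ``base`` is either patient-level cost summaries (perturbed CIs are
    recomputed from the perturbed distribution) or cohort margins
    (perturbed CIs unavailable).
    """
    params = params or ProductivityParameters()
    factors = scenario.component_factors(params)

    n, base_totals, _ = _cohort_stats(base)
    if isinstance(base, CohortMargins):
        perturbed: CohortBase = base.scale(factors)
    else:
        perturbed = perturb_summaries(base, factors)
    _, new_totals, new_sds = _cohort_stats(perturbed)

    def pct(row: str) -> float:
        b = base_totals[row]
        return (new_totals[row] - b) / b * 100.0 if b != 0 else 0.0

    return SensitivityResult(
        name=scenario.name,
        pct_change_total=pct("total"),
        pct_change_healthcare=pct("healthcare_total"),
        pct_change_sick_leave=pct("sick_leave"),
        new_total_mean=new_totals["total"] / n,
        new_healthcare_mean=new_totals["healthcare_total"] / n,
        ci95_total=ci95(new_totals["total"] / n, new_sds["total"], n),
        ci95_healthcare=ci95(
            new_totals["healthcare_total"] / n, new_sds["healthcare_total"], n
        ),
    )


def run_method_switch(
    base: CohortBase, params: ProductivityParameters | None = None
) -> SensitivityResult:
    """Revalue sick leave by the friction-cost method; healthcare unchanged."""
    params = params or ProductivityParameters()
    scenario = SensitivityScenario(
        name="Sick leave cost based on friction method",
        method_override=ValuationMethod.FRICTION,
    )
    return run_scenario(base, scenario, params)


def scenario_table(
    base: CohortBase,
    scenarios: Sequence[SensitivityScenario],
    params: ProductivityParameters | None = None,
) -> list[SensitivityResult]:
    """Run a list of scenarios, base-case row first, input order preserved."""
    if not scenarios:
        raise InputError("scenario_table requires at least one scenario")
    names = [s.name for s in scenarios]
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate scenario names: {sorted(dupes)}")
    base_row = run_scenario(base, SensitivityScenario(name="Base case scenario"), params)
    return [base_row] + [run_scenario(base, s, params) for s in scenarios]


def table6_scenarios() -> list[SensitivityScenario]:
    """The published deterministic scenario set.

    One-way: PT +/-30%, GP +/-50%, sick-leave day +/-30%, x-ray +/-30%,
    ultrasound +/-30%, medicine +100%/-50%.  Multi-way: PT & GP jointly,
    and PT, GP, x-ray & ultrasound jointly, both directions.  Plus the
    friction-method switch for sick leave.
    """
    S = SensitivityScenario
    return [
        S("PT cost per consultation +30%", {"pt_visit": 0.30}),
        S("PT cost per consultation -30%", {"pt_visit": -0.30}),
        S("GP cost per consultation +50%", {"gp_visit": 0.50}),
        S("GP cost per consultation -50%", {"gp_visit": -0.50}),
        S("Sick leave cost per day +30%", {"sick_leave_day": 0.30}),
        S("Sick leave cost per day -30%", {"sick_leave_day": -0.30}),
        S("X-ray cost per consultation +30%", {"xray": 0.30}),
        S("X-ray cost per consultation -30%", {"xray": -0.30}),
        S("Ultrasound cost per consultation +30%", {"ultrasound": 0.30}),
        S("Ultrasound cost per consultation -30%", {"ultrasound": -0.30}),
        S("Medicine unit cost +100%", {"medicine_per_prescription": 1.00}),
        S("Medicine unit cost -50%", {"medicine_per_prescription": -0.50}),
        S("PT +30%, GP +50%", {"pt_visit": 0.30, "gp_visit": 0.50}),
        S("PT -30%, GP -50%", {"pt_visit": -0.30, "gp_visit": -0.50}),
        S(
            "PT +30%, GP +50%, x-ray +30%, ultrasound +30%",
            {"pt_visit": 0.30, "gp_visit": 0.50, "xray": 0.30, "ultrasound": 0.30},
        ),
        S(
            "PT -30%, GP -50%, x-ray -30%, ultrasound -30%",
            {"pt_visit": -0.30, "gp_visit": -0.50, "xray": -0.30, "ultrasound": -0.30},
        ),
        S(
            "Sick leave cost based on friction method",
            method_override=ValuationMethod.FRICTION,
        ),
    ]
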