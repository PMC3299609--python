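"""Cohort-level cost margins: component totals, means and SDs.

A :class:`CohortMargins` carries, per cost component, the aggregate numbers
a published cost-of-illness table prints (unit counts, cost per patient
mean/SD, total cost).  Because the costing model is linear in unit prices,
these aggregates are a sufficient input for the sensitivity engine and for
confidence intervals -- patient-level records are only needed for medians,
quartiles and perturbed interval estimates.

:func:`load_paper_margins` returns the packaged study aggregates: the full
204-patient primary-care cohort and its 45-patient high-cost subgroup
(total cost > EUR 1000 over six months).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import COST_COMPONENTS, HEALTHCARE_COMPONENTS, PatientCostSummary
from .errors import InputError, PackagingError

__all__ = ["ComponentMargin", "CohortMargins", "PaperMarginsFixture", "load_paper_margins"]

_AGGREGATE_ROWS = ("healthcare_total", "total")
_ALL_ROWS = COST_COMPONENTS + _AGGREGATE_ROWS


@dataclass(frozen=True)
class ComponentMargin:
    """Aggregates for one cost component over a cohort."""

    total_cost: float
    cost_sd: float | None = None
    cost_mean: float | None = None  # printed (rounded) per-patient mean, if any
    mean_units: float | None = None
    sd_units: float | None = None
    total_units: float | None = None


@dataclass(frozen=True)
class CohortMargins:
    """Component-level aggregates for a cohort of ``n`` patients.

    ``mean(component)`` is always computed as total cost / n, at full
    precision; ``cost_mean`` on the rows keeps the printed (rounded) value
    when the margins come from a published table.
    """

    n: int
    components: Mapping[str, ComponentMargin]

    def __post_init__(self) -> None:
        missing = [c for c in _ALL_ROWS if c not in self.components]
        if missing:
            raise InputError(f"margins missing component rows: {missing}")

    def total_cost(self, component: str) -> float:
        return self.components[component].total_cost

    def mean(self, component: str) -> float:
        return self.total_cost(component) / self.n

    def sd(self, component: str) -> float | None:
        return self.components[component].cost_sd

    def scale(self, factors: Mapping[str, float]) -> "CohortMargins":
        """Rescale component total costs; aggregate rows are recomputed.

        Only the six base components can be scaled; printed per-patient
        means and SDs of scaled rows are dropped (no longer authoritative).
        """
        unknown = set(factors) - set(COST_COMPONENTS)
        if unknown:
            raise InputError(f"cannot scale non-component rows: {sorted(unknown)}")
        comps: dict[str, ComponentMargin] = {}
        for name in COST_COMPONENTS:
            row = self.components[name]
            f = factors.get(name, 1.0)
            if f == 1.0:
                comps[name] = row
            else:
                comps[name] = ComponentMargin(
                    total_cost=row.total_cost * f,
                    cost_sd=None if row.cost_sd is None else row.cost_sd * f,
                    mean_units=row.mean_units,
                    sd_units=row.sd_units,
                    total_units=row.total_units,
                )
        hc = sum(comps[c].total_cost for c in HEALTHCARE_COMPONENTS)
        sl = comps["sick_leave"].total_cost
        # Totals-row SDs are only known when nothing they cover was rescaled.
        hc_changed = any(factors.get(c, 1.0) != 1.0 for c in HEALTHCARE_COMPONENTS)
        sl_changed = factors.get("sick_leave", 1.0) != 1.0
        old_hc, old_tot = self.components["healthcare_total"], self.components["total"]
        comps["healthcare_total"] = ComponentMargin(
            total_cost=hc, cost_sd=None if hc_changed else old_hc.cost_sd
        )
        comps["total"] = ComponentMargin(
            total_cost=hc + sl,
            cost_sd=None if (hc_changed or sl_changed) else old_tot.cost_sd,
        )
        return replace(self, components=comps)

    @classmethod
    def from_summaries(cls, summaries: Sequence[PatientCostSummary]) -> "CohortMargins":
        """Aggregate patient-level cost summaries into cohort margins."""
        if not summaries:
            raise InputError("cannot build margins from an empty cohort")
        comps: dict[str, ComponentMargin] = {}
        for name in _ALL_ROWS:
            vals = np.array([s.component(name) for s in summaries], dtype=float)
            comps[name] = ComponentMargin(
                total_cost=float(vals.sum()),
                cost_sd=float(vals.std(ddof=1)) if len(vals) > 1 else None,
            )
        return cls(n=len(summaries), components=comps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in _ALL_ROWS:
            row = self.components[name]
            rows.append(
                {
                    "component": name,
                    "mean_units": row.mean_units,
                    "sd_units": row.sd_units,
                    "total_units": row.total_units,
                    "cost_per_patient": self.mean(name),
                    "cost_sd": row.cost_sd,
                    "total_cost": row.total_cost,
                }
            )
        return pd.DataFrame(rows).set_index("component")


@dataclass(frozen=True)
class PaperMarginsFixture:
    """Published aggregates: full cohort, high-cost subgroup, and the threshold."""

    full: CohortMargins
    high_cost: CohortMargins
    threshold: float = 1000.0


def _margins_from_rows(df: pd.DataFrame) -> CohortMargins:
    n = int(df["n"].iloc[0])
    comps = {}
    for _, r in df.iterrows():
        comps[r["component"]] = ComponentMargin(
            total_cost=float(r["total_cost"]),
            cost_sd=None if pd.isna(r["cost_sd"]) else float(r["cost_sd"]),
            cost_mean=None if pd.isna(r["cost_mean"]) else float(r["cost_mean"]),
            mean_units=None if pd.isna(r["mean_units"]) else float(r["mean_units"]),
            sd_units=None if pd.isna(r["sd_units"]) else float(r["sd_units"]),
            total_units=None if pd.isna(r["total_units"]) else float(r["total_units"]),
        )
    return CohortMargins(n=n, components=comps)


def load_paper_margins() -> PaperMarginsFixture:
    """Load the packaged study aggregates (read-only fixture).

    Raises :class:`PackagingError` if the resource is missing or its
    internal row sums no longer hold (healthcare + sick leave = total).
    """
    try:
        ref = resources.files("shouldercoi.data").joinpath("paper_margins.csv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise PackagingError(f"margins fixture unavailable: {exc}") from exc

    try:
        full = _margins_from_rows(df[df["group"] == "full"])
        high = _margins_from_rows(df[df["group"] == "high_cost"])
    except (KeyError, InputError, ValueError) as exc:
        raise PackagingError(f"margins fixture corrupted: {exc}") from exc

    for m in (full, high):
        hc_plus_sl = m.total_cost("healthcare_total") + m.total_cost("sick_leave")
        if abs(hc_plus_sl - m.total_cost("total")) > 0.5:
            raise PackagingError(
                "margins fixture corrupted: component totals do not sum to the grand total"
            )
    return PaperMarginsFixture(full=full, high_cost=high)
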