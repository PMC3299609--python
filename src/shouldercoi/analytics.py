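"""Cohort-level cost statistics, high-cost subgroups, concentration and regression.

Cost distributions in primary-care cohorts are strongly right-skewed: a
small minority of long-absence patients carries most of the burden.  The
descriptive report therefore pairs means/SDs with medians and quartiles,
and the concentration and subgroup reports quantify how much of the total
the most expensive patients account for.  Confidence intervals use the
z-normal approximation mean +/- 1.96 sd/sqrt(n), the convention the printed
intervals follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import PatientRecord, Sex
from .costing import COST_COMPONENTS, HEALTHCARE_COMPONENTS, PatientCostSummary
from .errors import InputError
from .margins import CohortMargins

__all__ = [
    "Z_95",
    "ComponentStats",
    "CohortCostReport",
    "SubgroupReport",
    "RegressionResult",
    "ci95",
    "summarize_cohort",
    "subgroup_report",
    "subgroup_report_from_margins",
    "concentration_share",
    "covariates_from_records",
    "fit_log_cost_regression",
]

Z_95 = 1.96

_REPORT_ROWS = COST_COMPONENTS + ("healthcare_total", "total")


def ci95(mean: float, sd: float | None, n: int) -> tuple[float, float] | None:
    """z-normal 95% CI for a mean; None when undefined (n < 2 or unknown SD)."""
    if sd is None or n < 2:
        return None
    half = Z_95 * sd / np.sqrt(n)
    return (mean - half, mean + half)


@dataclass(frozen=True)
class ComponentStats:
    mean: float
    sd: float | None
    grand_total: float
    ci95: tuple[float, float] | None
    median: float | None = None
    iqr: tuple[float, float] | None = None


@dataclass(frozen=True)
class CohortCostReport:
    """Descriptive cost statistics for a cohort, per component and overall."""

    n: int
    components: Mapping[str, ComponentStats]
    #: share of each healthcare component in total healthcare cost
    shares_of_healthcare: Mapping[str, float]
    #: share of each component (incl. sick leave) in total cost
    shares_of_total: Mapping[str, float]
    #: False when built from margins only (no patient-level quantiles)
    medians_available: bool

    def component(self, name: str) -> ComponentStats:
        return self.components[name]


def _shares(totals: Mapping[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    hc = totals["healthcare_total"]
    tot = totals["total"]
    shares_hc = {
        c: (totals[c] / hc if hc > 0 else 0.0) for c in HEALTHCARE_COMPONENTS
    }
    shares_tot = {c: (totals[c] / tot if tot > 0 else 0.0) for c in COST_COMPONENTS}
    return shares_hc, shares_tot


def summarize_cohort(
    summaries: Sequence[PatientCostSummary] | None = None,
    margins: CohortMargins | None = None,
) -> CohortCostReport:
    """Descriptive statistics from patient-level summaries or cohort margins.

    From margins, the mean is total/n, the SD is the one carried on the
    margins, and medians/IQRs are flagged unavailable.  With n < 2 the CI
    is reported as undefined rather than failing.
    """
    if (summaries is None) == (margins is None):
        raise InputError("provide exactly one of summaries or margins")

    comps: dict[str, ComponentStats] = {}
    if summaries is not None:
        n = len(summaries)
        if n == 0:
            raise InputError("cannot summarize an empty cohort")
        totals: dict[str, float] = {}
        for name in _REPORT_ROWS:
            vals = np.array([s.component(name) for s in summaries], dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else None
            q1, med, q3 = (float(q) for q in np.percentile(vals, [25, 50, 75]))
            comps[name] = ComponentStats(
                mean=mean,
                sd=sd,
                grand_total=float(vals.sum()),
                ci95=ci95(mean, sd, n),
                median=med,
                iqr=(q1, q3),
            )
            totals[name] = float(vals.sum())
        medians_available = True
    else:
        assert margins is not None
        n = margins.n
        totals = {name: margins.total_cost(name) for name in _REPORT_ROWS}
        for name in _REPORT_ROWS:
            mean = margins.mean(name)
            sd = margins.sd(name)
            comps[name] = ComponentStats(
                mean=mean,
                sd=sd,
                grand_total=totals[name],
                ci95=ci95(mean, sd, n),
            )
        medians_available = False

    shares_hc, shares_tot = _shares(totals)
    return CohortCostReport(
        n=n,
        components=comps,
        shares_of_healthcare=shares_hc,
        shares_of_total=shares_tot,
        medians_available=medians_available,
    )


@dataclass(frozen=True)
class SubgroupReport:
    """High-cost subgroup: patients whose total cost exceeds a threshold."""

    threshold: float
    n_subgroup: int
    report: CohortCostReport | None
    share_of_total_cost: float
    share_of_healthcare_cost: float


def subgroup_report(
    summaries: Sequence[PatientCostSummary], threshold: float
) -> SubgroupReport:
    """Report on the subgroup with total cost strictly above ``threshold``."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    sub = [s for s in summaries if s.total > threshold]
    cohort_total = sum(s.total for s in summaries)
    cohort_hc = sum(s.healthcare_total for s in summaries)
    if not sub:
        return SubgroupReport(threshold, 0, None, 0.0, 0.0)
    return SubgroupReport(
        threshold=threshold,
        n_subgroup=len(sub),
        report=summarize_cohort(summaries=sub),
        share_of_total_cost=sum(s.total for s in sub) / cohort_total,
        share_of_healthcare_cost=sum(s.healthcare_total for s in sub) / cohort_hc,
    )


def subgroup_report_from_margins(
    full: CohortMargins, subgroup: CohortMargins, threshold: float = 1000.0
) -> SubgroupReport:
    """Subgroup report when only published aggregates are available."""
    return SubgroupReport(
        threshold=threshold,
        n_subgroup=subgroup.n,
        report=summarize_cohort(margins=subgroup),
        share_of_total_cost=subgroup.total_cost("total") / full.total_cost("total"),
        share_of_healthcare_cost=(
            subgroup.total_cost("healthcare_total") / full.total_cost("healthcare_total")
        ),
    )


def concentration_share(totals: Sequence[float], top_fraction: float) -> float:
    """Cost share held by the ceil(top_fraction * n) most expensive patients."""
    if not 0 < top_fraction <= 1:
        raise InputError("top_fraction must be in (0, 1]")
    arr = np.asarray(totals, dtype=float)
    if arr.size == 0 or (arr < 0).any():
        raise InputError("totals must be non-empty and non-negative")
    grand = arr.sum()
    if grand == 0:
        raise InputError("concentration share undefined for all-zero totals")
    k = int(np.ceil(top_fraction * arr.size))
    return float(np.sort(arr)[::-1][:k].sum() / grand)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log cost on place of treatment, gender and age."""

    outcome: str
    params: Mapping[str, float]
    bse: Mapping[str, float]
    n_observations: int
    n_excluded_zero_cost: int


def covariates_from_records(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Regression covariates: place of treatment (municipality), gender, age."""
    places = sorted({r.municipality for r in records})
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "place": [float(places.index(r.municipality) > 0) if len(places) > 1 else 0.0
                      for r in records],
            "gender": [float(r.sex is Sex.FEMALE) for r in records],
            "age": [float(r.age) for r in records],
        }
    ).set_index("patient_id")


def fit_log_cost_regression(
    summaries: Sequence[PatientCostSummary],
    covariates: pd.DataFrame,
    outcome: str = "total",
) -> RegressionResult:
    """OLS of log(cost) on place, gender and age with an intercept.

    Patients with zero outcome cost are excluded from the log fit and
    counted in ``n_excluded_zero_cost``.  A rank-deficient design raises an
    error naming the collinear covariate.
    """
    if outcome not in ("total", "healthcare"):
        raise InputError(f"unknown regression outcome '{outcome}'")
    field = "total" if outcome == "total" else "healthcare_total"

    y_raw = pd.Series(
        {s.patient_id: s.component(field) for s in summaries}, name="cost"
    )
    df = covariates.join(y_raw, how="inner")
    nonzero = df["cost"] > 0
    n_excluded = int((~nonzero).sum())
    df = df[nonzero]
    if len(df) < 10:
        raise InputError(f"need >= 10 usable observations, have {len(df)}")

    X = sm.add_constant(df[["place", "gender", "age"]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for col in ("place", "gender", "age"):
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise InputError(f"design matrix is rank deficient: covariate '{col}' is collinear")
        raise InputError("design matrix is rank deficient")

    fit = sm.OLS(np.log(df["cost"].to_numpy()), X).fit()
    return RegressionResult(
        outcome=outcome,
        params=dict(fit.params),
        bse=dict(fit.bse),
        n_observations=int(fit.nobs),
        n_excluded_zero_cost=n_excluded,
    )
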