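"""Configuration and the end-to-end analysis pipeline.

Two input modes:

* **patient-level** -- read cohort tables from disk (or simulate them),
  apply inclusion criteria, build episodes, cost every patient bottom-up,
  then compute descriptive, subgroup and sensitivity reports;
* **margins** -- start from published cohort aggregates and reproduce the
  printed derived numbers (CIs, shares, sensitivity table, annual cost).

Rendered tables round euros half-up to whole euros and percentages to one
decimal; all intermediate computation stays at full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .analytics import (
    CohortCostReport,
    subgroup_report,
    subgroup_report_from_margins,
    summarize_cohort,
)
from .cohort import (
    DEFAULT_GAP_DAYS,
    PatientRecord,
    Window,
    assign_category,
    build_episode,
    include_patient,
    qualifying_visits,
)
from .costing import (
    COST_COMPONENTS,
    GradePolicy,
    ProductivityParameters,
    UnitCostSchedule,
    ValuationMethod,
    annualize,
    cost_cohort,
    estimate_secondary_costs,
    round_half_up,
)
from .errors import ConfigurationError
from .io import read_cohort, summaries_to_frame, write_cohort
from .margins import CohortMargins, load_paper_margins
from .sensitivity import (
    SensitivityResult,
    SensitivityScenario,
    scenario_table,
    table6_scenarios,
)
from .synthetic import CountDistParams, DurationDistParams, SyntheticCohortConfig, generate_cohort

__all__ = ["PipelineConfig", "load_config", "cmd_simulate", "cmd_analyze", "cmd_sensitivity"]

logger = logging.getLogger("shouldercoi")


class EpisodeSettings(BaseModel):
    gap_days: int = DEFAULT_GAP_DAYS
    holiday_start: Optional[date] = None
    holiday_end: Optional[date] = None


class SecondaryCareSettings(BaseModel):
    """Counts for the secondary-care estimate; referrals/surgeries fall back
    to the cohort's recorded counts in patient-level mode."""

    n_referrals: Optional[int] = None
    n_mri: int = 10
    n_surgeries: Optional[int] = None


class ScenarioSpec(BaseModel):
    name: str
    multipliers: dict[str, float] = Field(default_factory=dict)
    method: Optional[str] = None

    def build(self) -> SensitivityScenario:
        override = ValuationMethod(self.method) if self.method else None
        return SensitivityScenario(
            name=self.name, multipliers=self.multipliers, method_override=override
        )


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML/JSON file or keyword arguments)."""

    input_dir: Optional[str] = None
    synthetic: Optional[dict[str, Any]] = None
    window_start: date = date(2009, 1, 1)
    window_end: date = date(2009, 6, 30)
    unit_costs: dict[str, float] = Field(default_factory=dict)
    productivity: dict[str, Any] = Field(default_factory=dict)
    grade_policy: Literal["graded_weighting", "full_day"] = "graded_weighting"
    episode: EpisodeSettings = Field(default_factory=EpisodeSettings)
    secondary_care: SecondaryCareSettings = Field(default_factory=SecondaryCareSettings)
    subgroup_threshold: float = 1000.0
    scenarios: Literal["table6"] | list[ScenarioSpec] = "table6"
    outdir: str = "output"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_input_mode(self) -> "PipelineConfig":
        if self.input_dir is not None and self.synthetic is not None:
            raise ValueError("config must set at most one of input_dir / synthetic")
        return self

    # -- builders ----------------------------------------------------------

    @property
    def window(self) -> Window:
        return Window(self.window_start, self.window_end)

    def build_schedule(self) -> UnitCostSchedule:
        try:
            return UnitCostSchedule(**self.unit_costs)
        except TypeError as exc:
            raise ConfigurationError(f"unit_costs: {exc}") from exc

    def build_productivity(self) -> ProductivityParameters:
        kwargs = dict(self.productivity)
        if "valuation_method" in kwargs:
            kwargs["valuation_method"] = ValuationMethod(kwargs["valuation_method"])
        try:
            return ProductivityParameters(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"productivity: {exc}") from exc

    def build_synthetic_config(self) -> SyntheticCohortConfig:
        kwargs = dict(self.synthetic or {})
        if "gp_visits_dist" in kwargs:
            kwargs["gp_visits_dist"] = CountDistParams(**kwargs["gp_visits_dist"])
        if "pt_visits_dist" in kwargs:
            kwargs["pt_visits_dist"] = CountDistParams(**kwargs["pt_visits_dist"])
        if "sickleave_days_dist" in kwargs:
            kwargs["sickleave_days_dist"] = DurationDistParams(**kwargs["sickleave_days_dist"])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        if "category_weights" in kwargs:
            kwargs["category_weights"] = tuple(kwargs["category_weights"])
        kwargs.setdefault("window", self.window)
        kwargs.setdefault("seed", self.seed)
        try:
            return SyntheticCohortConfig(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"synthetic: {exc}") from exc

    def build_scenarios(self) -> list[SensitivityScenario]:
        if self.scenarios == "table6":
            return table6_scenarios()
        return [s.build() for s in self.scenarios]

    def holiday(self) -> Window | None:
        ep = self.episode
        if ep.holiday_start and ep.holiday_end:
            return Window(ep.holiday_start, ep.holiday_end)
        return None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# rendering helpers


def _eur(x: float | None) -> float | None:
    return None if x is None else round_half_up(x)


def _pct(x: float) -> float:
    return round_half_up(x, 1)


def _ci_str(ci: tuple[float, float] | None) -> str:
    if ci is None:
        return "undefined"
    return f"{_eur(ci[0]):.0f}-{_eur(ci[1]):.0f}"


def _report_frame(report: CohortCostReport) -> pd.DataFrame:
    rows = []
    for name in COST_COMPONENTS + ("healthcare_total", "total"):
        st = report.component(name)
        rows.append(
            {
                "component": name,
                "cost_per_patient": _eur(st.mean),
                "cost_sd": _eur(st.sd) if st.sd is not None else None,
                "total_cost": _eur(st.grand_total),
                "ci95": _ci_str(st.ci95),
                "median": _eur(st.median) if st.median is not None else None,
            }
        )
    return pd.DataFrame(rows)


def _sensitivity_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": r.name,
                "pct_change_total": _pct(r.pct_change_total),
                "pct_change_healthcare": _pct(r.pct_change_healthcare),
                "pct_change_sick_leave": _pct(r.pct_change_sick_leave),
                "total_mean": _eur(r.new_total_mean),
                "total_ci95": _ci_str(r.ci95_total),
                "healthcare_mean": _eur(r.new_healthcare_mean),
                "healthcare_ci95": _ci_str(r.ci95_healthcare),
            }
            for r in results
        ]
    )


def _setup_logging(config: PipelineConfig, outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    return handler


# ---------------------------------------------------------------------------
# commands


def cmd_simulate(config: PipelineConfig, seed: int | None = None) -> dict[str, Path]:
    """Generate a synthetic cohort and write it as four delimited tables,
    plus a provenance sidecar (config hash, seed, version)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = config.build_synthetic_config()
    used_seed = syn.seed if seed is None else seed
    records = generate_cohort(syn, seed=used_seed)
    paths = write_cohort(records, outdir)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": used_seed,
        "version": __version__,
        "n_patients": len(records),
        "mode": "synthetic",
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    paths["provenance.json"] = prov_path
    return paths


def _load_records(config: PipelineConfig, seed: int | None) -> list[PatientRecord]:
    if config.input_dir is not None:
        return read_cohort(config.input_dir)
    return generate_cohort(config.build_synthetic_config(), seed=seed)


def cmd_analyze(
    config: PipelineConfig, margins: bool = False, seed: int | None = None
) -> dict[str, Any]:
    """Run the full pipeline and write the report bundle.

    With ``margins=True`` the published aggregates replace patient-level
    data; medians, episode durations and perturbed CIs are then
    unavailable, which the reports mark explicitly.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(config, outdir)
    try:
        return _analyze(config, margins, seed, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _analyze(
    config: PipelineConfig, margins: bool, seed: int | None, outdir: Path
) -> dict[str, Any]:
    schedule = config.build_schedule()
    productivity = config.build_productivity()
    scenarios = config.build_scenarios()
    window = config.window
    mode = "margins" if margins else "patient-level"
    logger.info("analysis mode: %s; window %s..%s", mode, window.start, window.end)

    bundle: dict[str, Any] = {"mode": mode}
    summary: dict[str, Any] = {"mode": mode, "version": __version__, "config_hash": config.config_hash()}

    if margins:
        fixture = load_paper_margins()
        full: CohortMargins | None = fixture.full
        report = summarize_cohort(margins=fixture.full)
        sub = subgroup_report_from_margins(
            fixture.full, fixture.high_cost, threshold=fixture.threshold
        )
        sens_base: Any = fixture.full
        n = fixture.full.n
        sec = estimate_secondary_costs(
            config.secondary_care.n_referrals if config.secondary_care.n_referrals is not None else 29,
            config.secondary_care.n_mri,
            config.secondary_care.n_surgeries if config.secondary_care.n_surgeries is not None else 4,
            schedule,
        )
        durations_frame = None
    else:
        records = _load_records(config, seed)
        included = [r for r in records if include_patient(r, window)]
        logger.info("records read: %d; included: %d", len(records), len(included))
        episodes = [
            build_episode(qualifying_visits(r), window, config.episode.gap_days, config.holiday())
            for r in included
        ]
        duration_counts = (
            pd.Series([e.duration_category.value for e in episodes])
            .value_counts()
            .reindex(["w0_6", "w7_12", "w12_26", "gt_6m"], fill_value=0)
        )
        durations_frame = duration_counts.rename_axis("duration_category").reset_index(name="n")
        categories = pd.Series([assign_category(r, window).value for r in included])
        logger.info("episode duration counts: %s", duration_counts.to_dict())
        logger.info("diagnosis categories: %s", categories.value_counts().to_dict())

        summaries = cost_cohort(
            included, window, schedule, productivity, GradePolicy(config.grade_policy)
        )
        summaries_to_frame(summaries).to_csv(outdir / "patient_costs.csv", index=False)
        report = summarize_cohort(summaries=summaries)
        sub = subgroup_report(summaries, config.subgroup_threshold)
        sens_base = summaries
        full = None
        n = len(summaries)
        sec = estimate_secondary_costs(
            config.secondary_care.n_referrals
            if config.secondary_care.n_referrals is not None
            else sum(r.referrals for r in included),
            config.secondary_care.n_mri,
            config.secondary_care.n_surgeries
            if config.secondary_care.n_surgeries is not None
            else sum(r.surgeries for r in included),
            schedule,
        )
        bundle["records"] = included
        bundle["summaries"] = summaries
        summary["diagnosis_categories"] = categories.value_counts().to_dict()

    sens = scenario_table(sens_base, scenarios, productivity)

    table4 = _report_frame(report)
    table5 = (
        _report_frame(sub.report) if sub.report is not None else pd.DataFrame()
    )
    table6 = _sensitivity_frame(sens)
    table4.to_csv(outdir / "table4_costs.csv", index=False)
    table5.to_csv(outdir / "table5_highcost.csv", index=False)
    table6.to_csv(outdir / "table6_sensitivity.csv", index=False)
    if durations_frame is not None:
        durations_frame.to_csv(outdir / "table3_durations.csv", index=False)

    total = report.component("total")
    hc = report.component("healthcare_total")
    logger.info("total cost: %.2f over %d patients (mean %.2f)", total.grand_total, n, total.mean)
    logger.info("healthcare cost: %.2f (mean %.2f)", hc.grand_total, hc.mean)
    logger.info("secondary-care estimate: %.2f", sec)

    summary.update(
        {
            "n": n,
            "total_cost": total.grand_total,
            "total_mean": total.mean,
            "total_ci95": total.ci95,
            "healthcare_mean": hc.mean,
            "healthcare_ci95": hc.ci95,
            "annual_total_cost_per_patient": annualize(total.mean),
            "sick_leave_share_of_total": report.shares_of_total["sick_leave"],
            "pt_share_of_healthcare": report.shares_of_healthcare["pt"],
            "subgroup": {
                "threshold": sub.threshold,
                "n": sub.n_subgroup,
                "share_of_total_cost": sub.share_of_total_cost,
                "share_of_healthcare_cost": sub.share_of_healthcare_cost,
            },
            "secondary_care_estimate": sec,
        }
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")

    bundle.update(
        {
            "report": report,
            "subgroup": sub,
            "sensitivity": sens,
            "summary": summary,
            "tables": {
                "table4": table4,
                "table5": table5,
                "table6": table6,
                "table3": durations_frame,
            },
            "outdir": outdir,
        }
    )
    if full is not None:
        bundle["margins"] = full
    return bundle


def cmd_sensitivity(
    config: PipelineConfig, margins: bool = False, seed: int | None = None
) -> pd.DataFrame:
    """Run only the sensitivity engine and write the scenario table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    productivity = config.build_productivity()
    if margins:
        base: Any = load_paper_margins().full
    else:
        records = _load_records(config, seed)
        window = config.window
        included = [r for r in records if include_patient(r, window)]
        base = cost_cohort(
            included, window, config.build_schedule(), productivity,
            GradePolicy(config.grade_policy),
        )
    frame = _sensitivity_frame(scenario_table(base, config.build_scenarios(), productivity))
    frame.to_csv(outdir / "table6_sensitivity.csv", index=False)
    return frame
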