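"""Descriptive statistics, subgroup/concentration reports and the log-cost OLS."""

import numpy as np
import pandas as pd
import pytest

from shouldercoi import (
    CohortMargins,
    InputError,
    PatientCostSummary,
    concentration_share,
    covariates_from_records,
    cost_cohort,
    fit_log_cost_regression,
    subgroup_report,
    subgroup_report_from_margins,
    summarize_cohort,
)
from shouldercoi.costing import round_half_up


def _summary(pid: str, total: float) -> PatientCostSummary:
    return PatientCostSummary(patient_id=pid, pt=total)


class TestSummarizeCohort:
    def test_margins_reproduce_printed_total_ci(self, paper_margins):
        rep = summarize_cohort(margins=paper_margins.full)
        lo, hi = rep.component("total").ci95
        assert (round_half_up(lo), round_half_up(hi)) == (1283, 2856)

    def test_margins_reproduce_printed_healthcare_ci(self, paper_margins):
        rep = summarize_cohort(margins=paper_margins.full)
        lo, hi = rep.component("healthcare_total").ci95
        assert (round_half_up(lo), round_half_up(hi)) == (273, 380)

    def test_ci_half_width_formula(self, paper_margins):
        rep = summarize_cohort(margins=paper_margins.full)
        lo, hi = rep.component("total").ci95
        assert (hi - lo) / 2 == pytest.approx(1.96 * 5730 / np.sqrt(204))

    def test_margins_flag_missing_medians(self, paper_margins):
        rep = summarize_cohort(margins=paper_margins.full)
        assert not rep.medians_available
        assert rep.component("total").median is None

    def test_sample_statistics_by_hand(self):
        rep = summarize_cohort(summaries=[_summary("a", 100), _summary("b", 200), _summary("c", 300)])
        st = rep.component("total")
        assert st.mean == 200
        assert st.median == 200
        assert st.sd == pytest.approx(100.0)

    def test_single_patient_ci_undefined_without_failure(self):
        rep = summarize_cohort(summaries=[_summary("a", 100)])
        assert rep.component("total").ci95 is None

    def test_component_means_sum_to_total_mean(self, synthetic_summaries):
        rep = summarize_cohort(summaries=synthetic_summaries)
        parts = sum(
            rep.component(c).mean for c in ("gp", "pt", "xray", "ultrasound", "medicine", "sick_leave")
        )
        assert parts == pytest.approx(rep.component("total").mean)
        assert sum(rep.shares_of_total.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(rep.shares_of_healthcare.values()) == pytest.approx(1.0, abs=1e-9)

    def test_patient_level_and_derived_margins_agree(self, synthetic_summaries):
        """Summaries and margins computed from the same cohort give identical
        means, totals and CIs."""
        from_patients = summarize_cohort(summaries=synthetic_summaries)
        from_margins = summarize_cohort(margins=CohortMargins.from_summaries(synthetic_summaries))
        for name in ("gp", "pt", "sick_leave", "healthcare_total", "total"):
            a, b = from_patients.component(name), from_margins.component(name)
            assert a.mean == pytest.approx(b.mean)
            assert a.grand_total == pytest.approx(b.grand_total)
            assert a.ci95 == pytest.approx(b.ci95)


class TestSubgroupReport:
    def test_published_shares(self, paper_margins):
        rep = subgroup_report_from_margins(paper_margins.full, paper_margins.high_cost)
        assert rep.share_of_total_cost == pytest.approx(0.91, abs=0.005)
        assert rep.share_of_healthcare_cost == pytest.approx(0.44, abs=0.005)
        assert rep.n_subgroup == 45

    def test_threshold_above_everyone(self):
        rep = subgroup_report([_summary("a", 10), _summary("b", 20)], threshold=100)
        assert rep.n_subgroup == 0
        assert rep.share_of_total_cost == 0.0

    def test_strictly_greater_than_threshold(self):
        rep = subgroup_report([_summary("a", 1000), _summary("b", 1001)], threshold=1000)
        assert rep.n_subgroup == 1

    def test_shares_match_concentration_at_the_same_cut(self, synthetic_summaries):
        totals = sorted((s.total for s in synthetic_summaries), reverse=True)
        k = 41  # top fifth of 204
        threshold = (totals[k - 1] + totals[k]) / 2
        rep = subgroup_report(synthetic_summaries, threshold)
        assert rep.n_subgroup == k
        assert rep.share_of_total_cost == pytest.approx(
            concentration_share([s.total for s in synthetic_summaries], k / len(synthetic_summaries))
        )


class TestConcentrationShare:
    def test_whole_cohort(self):
        assert concentration_share([1, 2, 3], 1.0) == 1.0

    def test_uniform_costs(self):
        assert concentration_share([5.0] * 10, 0.2) == pytest.approx(0.2)

    def test_single_patient_holds_everything(self):
        assert concentration_share([1000.0] + [0.0] * 9, 0.1) == 1.0

    def test_monotone_in_top_fraction(self, synthetic_summaries):
        totals = [s.total for s in synthetic_summaries]
        shares = [concentration_share(totals, f) for f in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert shares == sorted(shares)
        assert shares[-1] == pytest.approx(1.0)

    def test_all_zero_is_undefined(self):
        with pytest.raises(InputError):
            concentration_share([0.0, 0.0], 0.2)


class TestLogCostRegression:
    @staticmethod
    def _simulated(n: int, gender_effect: float, seed: int):
        rng = np.random.default_rng(seed)
        gender = rng.integers(0, 2, n).astype(float)
        place = rng.integers(0, 2, n).astype(float)
        age = rng.integers(20, 65, n).astype(float)
        log_cost = 5.2 + gender_effect * gender + 0.8 * rng.standard_normal(n)
        summaries = [_summary(f"p{i}", float(np.exp(log_cost[i]))) for i in range(n)]
        cov = pd.DataFrame(
            {"place": place, "gender": gender, "age": age},
            index=[f"p{i}" for i in range(n)],
        ).rename_axis("patient_id")
        return summaries, cov

    def test_recovers_known_gender_effect(self):
        """A multiplicative gender effect e^0.5 is recovered at large n."""
        summaries, cov = self._simulated(2000, gender_effect=0.5, seed=11)
        res = fit_log_cost_regression(summaries, cov)
        assert res.params["gender"] == pytest.approx(0.5, abs=0.15)
        assert all(se > 0 for se in res.bse.values())

    def test_null_effects_on_generated_cohorts(self, default_config):
        """With no covariate effects built in, coefficients are within 2 SEs
        of zero in at least 90% of replicate cohorts."""
        hits, total = 0, 0
        for seed in range(30):
            from shouldercoi import generate_cohort

            recs = generate_cohort(default_config, seed=seed)
            summaries = cost_cohort(recs, default_config.window)
            res = fit_log_cost_regression(summaries, covariates_from_records(recs))
            for name in ("place", "gender", "age"):
                total += 1
                hits += abs(res.params[name]) < 2 * res.bse[name]
        assert hits / total >= 0.90

    def test_zero_cost_patients_excluded_and_counted(self):
        summaries, cov = self._simulated(50, gender_effect=0.0, seed=3)
        summaries[0] = PatientCostSummary(patient_id="p0")  # all-zero cost
        res = fit_log_cost_regression(summaries, cov)
        assert res.n_excluded_zero_cost == 1
        assert res.n_observations == 49

    def test_constant_covariate_is_reported_as_collinear(self):
        summaries, cov = self._simulated(50, gender_effect=0.0, seed=4)
        cov["place"] = 1.0  # indistinguishable from the intercept
        with pytest.raises(InputError, match="place"):
            fit_log_cost_regression(summaries, cov)

    def test_too_few_observations(self):
        summaries, cov = self._simulated(5, gender_effect=0.0, seed=5)
        with pytest.raises(InputError, match="10"):
            fit_log_cost_regression(summaries, cov)
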