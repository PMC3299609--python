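"""Deterministic sensitivity engine: linearity, superposition, published cells."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shouldercoi import (
    ConfigurationError,
    ProductivityParameters,
    SensitivityScenario,
    run_method_switch,
    run_scenario,
    scenario_table,
    table6_scenarios,
)
from shouldercoi.costing import round_half_up
from shouldercoi.sensitivity import UNIT_COST_TO_COMPONENT

UNIT_COSTS = sorted(UNIT_COST_TO_COMPONENT)


class TestScenarioValidation:
    def test_unknown_unit_cost_name(self):
        with pytest.raises(ConfigurationError, match="helicopter"):
            SensitivityScenario("bad", {"helicopter": 0.3})

    def test_multiplier_must_keep_price_positive(self):
        with pytest.raises(ConfigurationError):
            SensitivityScenario("bad", {"pt_visit": -1.0})

    def test_duplicate_scenario_names_rejected(self, paper_margins):
        scen = [SensitivityScenario("a", {"pt_visit": 0.1})] * 2
        with pytest.raises(ConfigurationError, match="duplicate"):
            scenario_table(paper_margins.full, scen)


class TestPublishedCells:
    def test_sick_leave_plus_30(self, paper_margins):
        r = run_scenario(paper_margins.full, SensitivityScenario("sl", {"sick_leave_day": 0.30}))
        assert round_half_up(r.pct_change_total, 1) == 25.3
        assert r.pct_change_healthcare == 0.0

    def test_pt_gp_multiway(self, paper_margins):
        r = run_scenario(
            paper_margins.full,
            SensitivityScenario("multi", {"pt_visit": 0.30, "gp_visit": 0.50}),
        )
        assert round_half_up(r.pct_change_healthcare, 1) == 32.6
        assert round_half_up(r.pct_change_total, 1) == 5.1

    def test_friction_switch_total(self, paper_margins):
        r = run_method_switch(paper_margins.full)
        assert round_half_up(r.new_total_mean) == 1001
        assert round_half_up(r.pct_change_total, 1) == -51.6
        assert round_half_up(r.pct_change_sick_leave, 1) == -61.3
        assert r.pct_change_healthcare == 0.0

    def test_friction_factor_one_is_identity(self, paper_margins):
        params = ProductivityParameters(friction_factor=1.0)
        r = run_method_switch(paper_margins.full, params)
        assert r.pct_change_total == 0.0
        assert r.new_total_mean == pytest.approx(paper_margins.full.mean("total"))


class TestIdentityAndStructure:
    def test_identity_scenario_is_a_fixed_point(self, paper_margins):
        base = paper_margins.full
        r = run_scenario(base, SensitivityScenario("identity"))
        assert r.pct_change_total == 0.0
        assert r.pct_change_healthcare == 0.0
        assert r.new_total_mean == base.mean("total")
        assert r.ci95_total is not None  # base-case CI still known from the margins

    def test_all_zero_multipliers_reproduce_base(self, synthetic_summaries):
        zero = SensitivityScenario("zeros", {k: 0.0 for k in UNIT_COSTS})
        r = run_scenario(synthetic_summaries, zero)
        assert r.pct_change_total == 0.0
        base = run_scenario(synthetic_summaries, SensitivityScenario("base"))
        assert r.new_total_mean == base.new_total_mean
        assert r.ci95_total == base.ci95_total

    def test_scenario_order_independence(self, paper_margins):
        scen = table6_scenarios()
        fwd = scenario_table(paper_margins.full, scen)[1:]
        rev = scenario_table(paper_margins.full, list(reversed(scen)))[1:]
        assert fwd == list(reversed(rev))

    def test_base_row_comes_first(self, paper_margins):
        rows = scenario_table(paper_margins.full, table6_scenarios())
        assert rows[0].pct_change_total == 0.0
        assert len(rows) == len(table6_scenarios()) + 1

    def test_healthcare_invariant_to_sick_leave_and_vice_versa(self, synthetic_summaries):
        base = run_scenario(synthetic_summaries, SensitivityScenario("base"))
        sl = run_scenario(synthetic_summaries, SensitivityScenario("sl", {"sick_leave_day": 0.7}))
        hc = run_scenario(synthetic_summaries, SensitivityScenario("hc", {"pt_visit": 0.7, "xray": -0.2}))
        assert sl.new_healthcare_mean == base.new_healthcare_mean
        assert sl.pct_change_healthcare == 0.0
        assert hc.pct_change_sick_leave == 0.0

    def test_margins_perturbed_ci_unavailable(self, paper_margins):
        r = run_scenario(paper_margins.full, SensitivityScenario("pt", {"pt_visit": 0.3}))
        assert r.ci95_healthcare is None
        # sick-leave untouched, so the total-cost SD is also unknown once HC moved
        assert r.ci95_total is None

    def test_patient_level_perturbed_ci_recomputed(self, synthetic_summaries):
        base = run_scenario(synthetic_summaries, SensitivityScenario("base"))
        r = run_scenario(synthetic_summaries, SensitivityScenario("pt", {"pt_visit": 0.3}))
        assert r.ci95_total is not None
        assert r.ci95_total != base.ci95_total


class TestLinearityOracle:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        key=st.sampled_from(UNIT_COSTS),
        delta=st.floats(min_value=-0.9, max_value=3.0).filter(lambda d: abs(d) > 1e-6),
    )
    def test_one_way_matches_closed_form_exactly(self, paper_margins, key, delta):
        """pct change = delta * (component total / grand total) * 100, to
        machine precision."""
        base = paper_margins.full
        comp = UNIT_COST_TO_COMPONENT[key]
        r = run_scenario(base, SensitivityScenario("s", {key: delta}))
        expected = delta * base.total_cost(comp) / base.total_cost("total") * 100.0
        np.testing.assert_allclose(r.pct_change_total, expected, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        d1=st.floats(min_value=-0.9, max_value=2.0),
        d2=st.floats(min_value=-0.9, max_value=2.0),
    )
    def test_superposition_of_multiway_scenarios(self, paper_margins, d1, d2):
        """A multi-way change equals the sum of its one-way constituents."""
        base = paper_margins.full
        both = run_scenario(base, SensitivityScenario("b", {"pt_visit": d1, "gp_visit": d2}))
        one = run_scenario(base, SensitivityScenario("1", {"pt_visit": d1}))
        two = run_scenario(base, SensitivityScenario("2", {"gp_visit": d2}))
        np.testing.assert_allclose(
            both.pct_change_total,
            one.pct_change_total + two.pct_change_total,
            rtol=1e-10,
            atol=1e-10,
        )

    def test_margins_and_patient_level_agree(self, synthetic_summaries):
        """Running a scenario on patient-level data or on the margins derived
        from it gives the same percent changes."""
        from shouldercoi import CohortMargins

        margins = CohortMargins.from_summaries(synthetic_summaries)
        scen = SensitivityScenario("s", {"pt_visit": 0.3, "sick_leave_day": -0.2})
        a = run_scenario(synthetic_summaries, scen)
        b = run_scenario(margins, scen)
        assert a.pct_change_total == pytest.approx(b.pct_change_total, rel=1e-12)
        assert a.new_total_mean == pytest.approx(b.new_total_mean, rel=1e-12)
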