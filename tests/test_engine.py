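"""The yearly recursion: carryover, accounting identity, scenarios,
sensitivity, and an independent hand-unrolled oracle."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careforce import (
    GroupParameters,
    GrowthSchedule,
    OccupationGroup,
    Override,
    ParameterSet,
    ScenarioSpec,
    ShockSchedule,
    SupplyRule,
    ValidationError,
    WorkforceState,
    deficit,
    initial_state,
    load_baseline,
    packaged_scenarios,
    pct_graduates_hired,
    project,
    run_scenarios,
    sensitivity_sweep,
    step,
    vacancy_rate,
)

RN, LPN, HCA = OccupationGroup.RN, OccupationGroup.LPN, OccupationGroup.HCA


def toy_parameter_set(**rn_kw) -> ParameterSet:
    """A small three-group system with simple round numbers."""
    rn = dict(
        budgeted_fte=1000,
        avg_fte=1.0,
        separation_rate=0.10,
        target_vacancy_rate=0.0,
        retention_rate=1.0,
        graduates_per_year=50,
    )
    rn.update(rn_kw)
    groups = {
        RN: GroupParameters(**rn),
        LPN: GroupParameters(
            budgeted_fte=300,
            avg_fte=1.0,
            separation_rate=0.05,
            target_vacancy_rate=0.0,
            retention_rate=1.0,
            graduates_per_year=100,
        ),
        HCA: GroupParameters(
            budgeted_fte=200,
            avg_fte=1.0,
            separation_rate=0.05,
            target_vacancy_rate=0.0,
            supply_rule=SupplyRule.MIRROR_DEMAND,
        ),
    }
    years = range(2010, 2021)
    return ParameterSet(
        groups=groups,
        growth=GrowthSchedule({y: 0.0 for y in years}),
        shock=ShockSchedule({}),
        horizon=(2010, 2020),
    )


class TestElementaryOps:
    @pytest.mark.parametrize(
        "demand, supply, expected",
        [(3244, 1107, -2137), (250, 799, 549), (640, 640, 0)],
    )
    def test_signed_surplus(self, demand, supply, expected):
        assert deficit(demand, supply) == expected

    @pytest.mark.parametrize(
        "demand, graduates, cap, expected",
        [(620, 802, 0.90, 0.77), (250, 802, 0.90, 0.31), (10000, 802, 0.90, 0.90)],
    )
    def test_share_of_class_hired(self, demand, graduates, cap, expected):
        assert pct_graduates_hired(demand, graduates, cap) == pytest.approx(
            expected, abs=0.005
        )

    def test_no_pipeline_is_undefined(self):
        assert pct_graduates_hired(100, 0, 0.9) is None

    @pytest.mark.parametrize(
        "unfilled, budgeted, expected",
        [(0, 10000, 0.0), (500, 10000, 0.05), (12000, 10000, 1.0)],
    )
    def test_vacancy_rate_clipped(self, unfilled, budgeted, expected):
        assert vacancy_rate(unfilled, budgeted) == expected

    def test_vacancy_rate_zero_denominator(self):
        with pytest.raises(ValidationError):
            vacancy_rate(100, 0)


class TestStep:
    def test_zero_rates_are_a_fixed_point(self):
        p = GroupParameters(
            budgeted_fte=1000,
            avg_fte=1.0,
            separation_rate=0.0,
            target_vacancy_rate=0.0,
            retention_rate=1.0,
            graduates_per_year=0,
        )
        state = initial_state(p, 2010)
        nxt, row = step(state, p, RN, 2010, growth_rate=0.0, shock_rate=0.0)
        assert (row.demand, row.supply, row.surplus_deficit) == (0, 0, 0)
        assert nxt.filled_fte == state.filled_fte
        assert nxt.budgeted_fte == state.budgeted_fte
        assert nxt.cumulative_deficit == 0

    def test_mirror_demand_group_never_runs_a_deficit(self, baseline):
        state = initial_state(baseline.HCA, 2010)
        _, row = step(state, baseline.HCA, HCA, 2010, 0.0256, 0.0)
        assert row.supply == row.demand
        assert row.surplus_deficit == 0
        assert row.pct_graduates_hired is None

    def test_toy_shortfall_becomes_carryover(self):
        # 1000 FTE at avg 1.0, 10% separations, no growth, supply 50
        # -> demand 100, deficit -50, next carryover 50
        p = GroupParameters(
            budgeted_fte=1000,
            avg_fte=1.0,
            separation_rate=0.10,
            target_vacancy_rate=0.0,
            retention_rate=1.0,
            graduates_per_year=50,
        )
        state = WorkforceState(
            year=2010, filled_fte=1000, headcount=1000, budgeted_fte=1000
        )
        nxt, row = step(state, p, RN, 2010, growth_rate=0.0, shock_rate=0.0)
        assert row.demand == 100
        assert row.surplus_deficit == -50
        assert nxt.cumulative_deficit == 50

    def test_accounting_identity(self):
        p = GroupParameters(
            budgeted_fte=5000,
            avg_fte=0.8,
            separation_rate=0.06,
            target_vacancy_rate=0.03,
            retention_rate=0.8,
            graduates_per_year=400,
        )
        state = initial_state(p, 2010)
        for year, (g, s) in enumerate(
            [(0.02, 0.0), (0.025, 0.0663), (0.022, 0.0)], start=2010
        ):
            nxt, row = step(state, p, RN, year, g, s)
            c = row.components
            hires = min(row.supply_exact, row.demand_exact)
            shock_fte = c.shock * p.avg_fte
            expected = (
                state.filled_fte
                + hires * p.avg_fte
                - c.replacement * p.avg_fte
                - shock_fte
            )
            assert nxt.filled_fte == pytest.approx(expected, abs=1e-6)
            assert nxt.headcount * p.avg_fte == pytest.approx(nxt.filled_fte, abs=1e-6)
            state = nxt


class TestProject:
    def test_empty_horizon_gives_empty_run(self, baseline):
        run = project(baseline, horizon=(2012, 2011))
        assert all(len(rows) == 0 for rows in run.rows.values())

    def test_constant_shortfall_accumulates_linearly(self):
        # intrinsic shortfall of d=50/year with carryover compounding the
        # demand but not the gap: cumulative deficit after n years = n*d
        params = toy_parameter_set()
        p = params.RN
        state = initial_state(p, 2010)
        for n, year in enumerate(range(2010, 2021), start=1):
            fixed_demand = 100 + state.cumulative_deficit  # d=50 over supply 50
            state, row = step(
                state, p, RN, year, 0.0, 0.0, fixed_demand=fixed_demand, fixed_supply=50
            )
            assert state.cumulative_deficit == pytest.approx(50 * n)

    def test_surpluses_are_not_banked_as_supply(self):
        params = toy_parameter_set()
        run = project(params)
        lpn_rows = run.rows[LPN]
        # supply 100 vs demand ~15 each year: the surplus stays yearly
        assert all(r.surplus_deficit > 0 for r in lpn_rows)
        assert all(r.supply == 100 for r in lpn_rows)

    def test_no_deficit_keeps_vacancy_at_target(self):
        params = toy_parameter_set(
            separation_rate=0.02, graduates_per_year=500, target_vacancy_rate=0.03
        )
        run = project(params)
        for r in run.rows[RN]:
            assert r.surplus_deficit >= 0
            assert r.fte_vacancy_rate == pytest.approx(0.03)
        assert run.summary[RN].cumulative_deficit == 0

    def test_determinism_bit_identical(self, baseline):
        assert project(baseline) == project(baseline)

    def test_three_year_hand_unrolled_oracle(self):
        """Independent re-implementation of the recursion on a toy system."""
        p = GroupParameters(
            budgeted_fte=1000,
            avg_fte=0.8,
            separation_rate=0.10,
            target_vacancy_rate=0.0,
            retention_rate=1.0,
            graduates_per_year=40,
        )
        growth = {2010: 0.02, 2011: 0.03, 2012: 0.0}
        shock = {2011: 0.05}
        # --- oracle: plain loop written independently of the engine ---
        from careforce.rounding import round_half_up

        filled, budget, carry = 1000.0, 1000.0, 0.0
        expected = []
        for y in [2010, 2011, 2012]:
            head = filled / 0.8
            repl = round_half_up(head * 0.10)
            grow = filled * growth[y] / 0.8
            shk_fte = filled * shock.get(y, 0.0)
            shk = shk_fte / 0.8
            gap = max(0.0, (budget - filled) - carry * 0.8) / 0.8
            demand = repl + grow + shk + gap + carry
            supply = 40.0
            carry = max(0.0, demand - supply)
            hires = min(supply, demand)
            filled = max(0.0, filled + hires * 0.8 - repl * 0.8 - shk_fte)
            budget = budget * (1 + growth[y])
            expected.append((round_half_up(demand), carry, filled, budget))
        # --- engine ---
        state = initial_state(p, 2010)
        for y, (exp_demand, exp_carry, exp_filled, exp_budget) in zip(
            [2010, 2011, 2012], expected
        ):
            state, row = step(state, p, RN, y, growth[y], shock.get(y, 0.0))
            assert row.demand == exp_demand
            assert state.cumulative_deficit == pytest.approx(exp_carry)
            assert state.filled_fte == pytest.approx(exp_filled)
            assert state.budgeted_fte == pytest.approx(exp_budget)


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(delta=st.floats(0.001, 0.02))
    def test_deficit_grows_with_separation_rate(self, delta):
        base = load_baseline()
        hi = ScenarioSpec(
            name="hi", overrides=(Override(RN, "separation_rate", 0.0450 + delta),)
        )
        run_lo, run_hi = project(base), project(base, hi)
        for lo, hi_row in zip(run_lo.rows[RN], run_hi.rows[RN]):
            assert -hi_row.surplus_deficit >= -lo.surplus_deficit

    def test_deficit_shrinks_with_more_graduates(self, baseline):
        more = ScenarioSpec(
            name="more-grads", overrides=(Override(RN, "graduates_per_year", 2500),)
        )
        run_lo, run_hi = project(baseline), project(baseline, more)
        for lo, hi in zip(run_lo.rows[RN], run_hi.rows[RN]):
            assert -hi.surplus_deficit <= -lo.surplus_deficit

    def test_deficit_shrinks_with_higher_retention(self, baseline):
        more = ScenarioSpec(
            name="retain-all", overrides=(Override(RN, "retention_rate", 1.0),)
        )
        run_lo, run_hi = project(baseline), project(baseline, more)
        assert (
            run_hi.summary[RN].cumulative_deficit
            <= run_lo.summary[RN].cumulative_deficit
        )

    def test_deficit_grows_with_population_growth(self, baseline):
        faster = ScenarioSpec(
            name="faster",
            overrides=(
                Override(None, "growth", {y: 0.04 for y in range(2010, 2021)}),
            ),
        )
        run_lo, run_hi = project(baseline), project(baseline, faster)
        for lo, hi in zip(run_lo.rows[RN], run_hi.rows[RN]):
            assert -hi.surplus_deficit >= -lo.surplus_deficit


class TestScenarios:
    def test_six_packaged_scenarios(self):
        specs = packaged_scenarios()
        assert len(specs) == 6
        assert specs[0].name == "baseline"

    def test_baseline_spec_reproduces_plain_projection(self, baseline):
        runs = run_scenarios(baseline, [packaged_scenarios()[0]])
        assert len(runs) == 1
        plain = project(baseline)
        assert runs[0].rows == plain.rows

    def test_full_time_work_lowers_headcount_demand(self, baseline):
        full_time = ScenarioSpec(
            name="ft",
            overrides=tuple(
                Override(g, "avg_fte", 1.0) for g in OccupationGroup
            ),
        )
        run_base, run_ft = project(baseline), project(baseline, full_time)
        for g in OccupationGroup:
            for lo, hi in zip(run_ft.rows[g], run_base.rows[g]):
                assert lo.demand <= hi.demand

    def test_retirement_doubling_raises_deficit_every_year(self, baseline):
        doubled = ScenarioSpec(
            name="2x",
            overrides=tuple(
                Override(g, "separation_rate", 2 * baseline[g].separation_rate)
                for g in OccupationGroup
            ),
        )
        run_base, run_hi = project(baseline), project(baseline, doubled)
        for lo, hi in zip(run_base.rows[RN], run_hi.rows[RN]):
            assert -hi.surplus_deficit >= -lo.surplus_deficit

    def test_invalid_spec_aborts_with_name(self, baseline):
        bad = ScenarioSpec(name="broken", overrides=(Override(RN, "nope", 1),))
        with pytest.raises(Exception, match="broken"):
            run_scenarios(baseline, [bad])

    def test_all_packaged_scenarios_run(self, baseline):
        runs = run_scenarios(baseline, packaged_scenarios())
        assert [r.scenario for r in runs] == [s.name for s in packaged_scenarios()]
        for run in runs:
            for g in OccupationGroup:
                assert len(run.rows[g]) == 11


class TestSensitivity:
    def test_empty_override_list_gives_zero_deltas(self, baseline):
        res = sensitivity_sweep(baseline, [])
        assert all(d == 0 for d in res.deficit_delta.values())
        assert all(d == 0 for d in res.surplus_delta.values())

    def test_lower_turnover_helps_every_year(self, baseline):
        res = sensitivity_sweep(
            baseline,
            [
                ("RN.separation_rate", 0.0343),
                ("LPN.separation_rate", 0.0416),
                ("HCA.separation_rate", 0.0593),
            ],
        )
        for lo, hi in zip(res.adjusted.rows[RN], res.baseline.rows[RN]):
            assert -lo.surplus_deficit < -hi.surplus_deficit
        for lo, hi in zip(res.adjusted.rows[LPN], res.baseline.rows[LPN]):
            assert lo.surplus_deficit > hi.surplus_deficit
        assert res.deficit_delta[RN] < 0
        assert res.surplus_delta[LPN] > 0

    def test_more_graduates_weakly_reduce_deficit(self, baseline):
        res = sensitivity_sweep(baseline, [("RN.graduates_per_year", 2000)])
        for adj, base in zip(res.adjusted.rows[RN], res.baseline.rows[RN]):
            assert -adj.surplus_deficit <= -base.surplus_deficit
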