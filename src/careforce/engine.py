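"""The yearly projection recursion, scenarios, and sensitivity sweeps.

The model is a deterministic stock-and-flow recursion.  Each year a
group's demand for new staff is built from replacement of separations,
service growth, the casual add-on, the economic-recovery shock, the gap
to the target vacancy rate, and the previous year's unfilled shortfall
(carryover).  Supply is the retained graduating class (HCA supply mirrors
demand).  Any shortfall carries over, undiminished, into next year's
demand; surpluses are not banked as future supply.

A *calibration mode* accepts externally fixed demand and/or supply
streams per group, so the downstream arithmetic — deficits, carryover,
vacancy rates, hiring percentages, cumulative totals — can be driven
directly from a published projection table rather than from the demand
reconstruction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .demand import DemandComponents, demand_step
from .parameters import (
    GroupParameters,
    OccupationGroup,
    Override,
    ParameterSet,
    ScenarioSpec,
    ValidationError,
    WorkforceState,
    apply_scenario,
)
from .rounding import round_half_up
from .supply import annual_supply

__all__ = [
    "ProjectionRow",
    "ProjectionRun",
    "GroupSummary",
    "SensitivityResult",
    "deficit",
    "pct_graduates_hired",
    "vacancy_rate",
    "initial_state",
    "step",
    "project",
    "run_scenarios",
    "sensitivity_sweep",
    "packaged_scenarios",
    "summarize_rows",
]


# ---------------------------------------------------------------------------
# Elementary accounting operations
# ---------------------------------------------------------------------------

def deficit(demand: float, supply: float) -> float:
    """Signed surplus: ``supply - demand`` (negative means a shortfall)."""
    if demand < 0 or supply < 0:
        raise ValidationError("demand and supply must be non-negative")
    return supply - demand


def pct_graduates_hired(demand: float, graduates: float, cap: float) -> float | None:
    """Fraction of the graduating class absorbed by demand, capped at the
    retention rate.  ``None`` (undefined) when there is no pipeline."""
    if graduates == 0:
        return None
    if graduates < 0 or demand < 0:
        raise ValidationError("demand and graduates must be non-negative")
    if not (0 <= cap <= 1):
        raise ValidationError(f"cap must be in [0, 1], got {cap}")
    return min(demand / graduates, cap)


def vacancy_rate(unfilled_fte: float, budgeted_fte: float) -> float:
    """Unfilled over budgeted FTE, clipped to [0, 1]."""
    if budgeted_fte <= 0:
        raise ValidationError(f"budgeted_fte must be > 0, got {budgeted_fte}")
    if unfilled_fte < 0:
        raise ValidationError(f"unfilled_fte must be >= 0, got {unfilled_fte}")
    return min(unfilled_fte / budgeted_fte, 1.0)


# ---------------------------------------------------------------------------
# Rows, runs, summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionRow:
    """One group-year of the projection table.

    ``demand``/``supply``/``surplus_deficit`` are whole persons (rounding
    happens at reporting time; ``demand_exact``/``supply_exact`` keep the
    unrounded values used by the state fold).  ``components`` is the
    additive demand breakdown; it is ``None`` in calibration mode, where
    demand is externally fixed and not decomposed.
    """

    year: int
    group: OccupationGroup
    demand: int
    supply: int
    surplus_deficit: int
    fte_vacancy_rate: float
    pct_graduates_hired: float | None
    demand_exact: float
    supply_exact: float
    components: DemandComponents | None = None


@dataclass(frozen=True)
class GroupSummary:
    """End-of-horizon summary for one group, recomputable from its rows.

    Deficits compound through carryover, so the cumulative deficit is the
    final year's shortfall; surpluses are not banked, so the cumulative
    surplus is the sum of the yearly surpluses.
    """

    cumulative_deficit: int
    cumulative_surplus: int
    end_vacancy_rate: float
    cap_binding_years: tuple[int, ...]


def summarize_rows(rows: Sequence[ProjectionRow]) -> GroupSummary:
    """Aggregate a group's yearly rows into its horizon summary."""
    rows = tuple(rows)
    if not rows:
        return GroupSummary(0, 0, 0.0, ())
    last = rows[-1]
    cap_years = tuple(
        r.year for r in rows if r.pct_graduates_hired is not None and r.demand > r.supply
    )
    return GroupSummary(
        cumulative_deficit=max(0, -last.surplus_deficit),
        cumulative_surplus=sum(max(0, r.surplus_deficit) for r in rows),
        end_vacancy_rate=last.fte_vacancy_rate,
        cap_binding_years=cap_years,
    )


@dataclass(frozen=True)
class ProjectionRun:
    """A complete scenario projection: per-group yearly rows plus summary."""

    scenario: str
    horizon: tuple[int, int]
    rows: Mapping[OccupationGroup, tuple[ProjectionRow, ...]]
    summary: Mapping[OccupationGroup, GroupSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", {g: tuple(r) for g, r in self.rows.items()})
        if not self.summary:
            object.__setattr__(
                self, "summary", {g: summarize_rows(r) for g, r in self.rows.items()}
            )
        else:
            object.__setattr__(self, "summary", dict(self.summary))


# ---------------------------------------------------------------------------
# The recursion
# ---------------------------------------------------------------------------

def initial_state(params: GroupParameters, year: int) -> WorkforceState:
    """Year-0 state: the workforce sits at its target vacancy rate.

    Filled FTE is budgeted FTE less the target vacancy allowance; head
    count follows from the group's average FTE.
    """
    filled = params.budgeted_fte * (1 - params.target_vacancy_rate)
    return WorkforceState(
        year=year,
        filled_fte=filled,
        headcount=filled / params.avg_fte,
        cumulative_deficit=0.0,
        budgeted_fte=params.budgeted_fte,
    )


def step(
    state: WorkforceState,
    params: GroupParameters,
    group: OccupationGroup,
    year: int,
    growth_rate: float,
    shock_rate: float,
    *,
    fixed_demand: float | None = None,
    fixed_supply: float | None = None,
) -> tuple[WorkforceState, ProjectionRow]:
    """Advance one group one year; return the next state and the row.

    The change in the employed stock is the gap between staff demanded
    and staff supplied: filled FTE moves by hires minus separations minus
    the shock withdrawal, funded positions grow with the demand growth
    rate, and any unmet demand becomes next year's carryover.

    ``fixed_demand``/``fixed_supply`` (persons) switch on calibration
    mode for the respective side of the ledger.
    """
    budgeted = state.budgeted_fte if state.budgeted_fte is not None else params.budgeted_fte
    params_now = dataclasses.replace(params, budgeted_fte=budgeted)

    if fixed_demand is not None:
        # the fixed stream already embeds its own carryover and shock
        components = None
        demand_persons = float(fixed_demand)
        shock_fte = 0.0
        separations_persons = 0.0
    else:
        components = demand_step(state, params_now, growth_rate, shock_rate)
        demand_persons = components.total
        shock_fte = components.shock * params.avg_fte
        separations_persons = components.replacement

    if fixed_supply is not None:
        supply_persons = float(fixed_supply)
        mirror = False
    else:
        sc = annual_supply(params_now, year)
        mirror = sc.mirror_demand
        supply_persons = demand_persons if mirror else float(sc.new_graduate_hires)

    if mirror or params.graduates_per_year in (None, 0):
        hired_pct = None
    else:
        hired_pct = pct_graduates_hired(
            round_half_up(demand_persons),
            params.graduates_per_year,
            params.retention_rate if params.retention_rate is not None else 1.0,
        )

    gap = deficit(demand_persons, supply_persons)
    next_carryover = max(0.0, -gap)

    # stock update: hires cannot exceed what is demanded
    hires = min(supply_persons, demand_persons)
    filled_next = max(
        0.0,
        state.filled_fte
        + hires * params.avg_fte
        - separations_persons * params.avg_fte
        - shock_fte,
    )
    budgeted_next = budgeted * (1 + growth_rate)

    vac = vacancy_rate(
        params.target_vacancy_rate * budgeted + next_carryover * params.avg_fte,
        budgeted,
    )

    demand_r = round_half_up(demand_persons)
    supply_r = round_half_up(supply_persons)
    row = ProjectionRow(
        year=year,
        group=group,
        demand=demand_r,
        supply=supply_r,
        surplus_deficit=supply_r - demand_r,
        fte_vacancy_rate=vac,
        pct_graduates_hired=hired_pct,
        demand_exact=demand_persons,
        supply_exact=supply_persons,
        components=components,
    )
    next_state = WorkforceState(
        year=year + 1,
        filled_fte=filled_next,
        headcount=filled_next / params.avg_fte,
        cumulative_deficit=next_carryover,
        budgeted_fte=budgeted_next,
    )
    return next_state, row


Streams = Mapping[OccupationGroup, Mapping[int, float]]


def project(
    params: ParameterSet,
    scenario: ScenarioSpec | None = None,
    horizon: tuple[int, int] | None = None,
    *,
    demand_streams: Streams | None = None,
    supply_streams: Streams | None = None,
) -> ProjectionRun:
    """Fold the yearly recursion over the horizon for all three groups.

    The model is fully deterministic: identical inputs produce identical
    runs.  ``demand_streams``/``supply_streams`` (``{group: {year:
    persons}}``) activate calibration mode for the covered group-years.
    """
    if scenario is not None:
        params = apply_scenario(params, scenario)
    start, end = horizon if horizon is not None else params.horizon
    name = scenario.name if scenario is not None else "baseline"
    if end < start:
        return ProjectionRun(scenario=name, horizon=(start, end), rows={g: () for g in OccupationGroup})

    demand_streams = demand_streams or {}
    supply_streams = supply_streams or {}
    rows: dict[OccupationGroup, list[ProjectionRow]] = {}
    for group in OccupationGroup:
        gp = params[group]
        state = initial_state(gp, start)
        d_stream = demand_streams.get(group, {})
        s_stream = supply_streams.get(group, {})
        group_rows: list[ProjectionRow] = []
        for year in range(start, end + 1):
            state, row = step(
                state,
                gp,
                group,
                year,
                params.growth[year],
                params.shock[year],
                fixed_demand=d_stream.get(year),
                fixed_supply=s_stream.get(year),
            )
            group_rows.append(row)
        rows[group] = group_rows
    return ProjectionRun(scenario=name, horizon=(start, end), rows=rows)


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

def packaged_scenarios() -> list[ScenarioSpec]:
    """The six policy scenarios shipped with the model.

    1. Baseline — continuation of the status quo.
    2. Right care, right place — aged-care services shift work from the
       RN pool toward HCAs (skill-mix change).
    3. Full-time work for full-time pay — higher average FTE worked, so
       fewer persons are needed per funded FTE.
    4. Retirement impact — an ageing workforce raises separation rates.
    5. Right care, right place, right skill (i) — expansion of the LPN
       share of the care workforce.
    6. Right care, right place, right skill (ii) — expansion of the HCA
       share of the care workforce.

    The skill-mix and rate adjustments are package defaults (five-point
    share shifts, +1 percentage point on separation, +0.1 on average
    FTE); every figure can be overridden through scenario configs.
    """
    RN, LPN, HCA = OccupationGroup.RN, OccupationGroup.LPN, OccupationGroup.HCA
    return [
        ScenarioSpec(name="baseline", description="Continuation of the status quo."),
        ScenarioSpec(
            name="right-care-right-place",
            description="Aged-care redesign shifts five points of skill mix from RNs to HCAs.",
            overrides=(
                Override(None, "skill_mix", {"RN": 0.656, "LPN": 0.147, "HCA": 0.197}),
            ),
        ),
        ScenarioSpec(
            name="full-time-work",
            description="Average FTE worked rises by 0.1 in every group.",
            overrides=(
                Override(RN, "avg_fte", 0.783),
                Override(LPN, "avg_fte", 0.799),
                Override(HCA, "avg_fte", 0.525),
            ),
        ),
        ScenarioSpec(
            name="retirement-impact",
            description="Ageing workforce: separation rates rise one percentage point.",
            overrides=(
                Override(RN, "separation_rate", 0.0550),
                Override(LPN, "separation_rate", 0.0679),
                Override(HCA, "separation_rate", 0.0866),
            ),
        ),
        ScenarioSpec(
            name="lpn-expansion",
            description="Right skill (i): ten points of skill mix move from RNs to LPNs.",
            overrides=(
                Override(None, "skill_mix", {"RN": 0.606, "LPN": 0.247, "HCA": 0.147}),
            ),
        ),
        ScenarioSpec(
            name="hca-expansion",
            description="Right skill (ii): ten points of skill mix move from RNs to HCAs.",
            overrides=(
                Override(None, "skill_mix", {"RN": 0.606, "LPN": 0.147, "HCA": 0.247}),
            ),
        ),
    ]


def run_scenarios(
    params: ParameterSet, specs: Sequence[ScenarioSpec]
) -> list[ProjectionRun]:
    """Project every scenario against the same base, preserving order."""
    return [project(params, spec) for spec in specs]


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    """Baseline-versus-adjusted comparison for a one-at-a-time sweep.

    Deltas are adjusted minus baseline; a negative deficit delta means
    the adjustment shrinks the shortfall.
    """

    baseline: ProjectionRun
    adjusted: ProjectionRun
    deficit_delta: Mapping[OccupationGroup, int]
    surplus_delta: Mapping[OccupationGroup, int]
    end_vacancy_delta: Mapping[OccupationGroup, float]


def _parse_override_path(path: str, value) -> Override:
    head, _, rest = path.partition(".")
    try:
        group = OccupationGroup(head)
    except ValueError:
        if rest:
            raise
        return Override(None, head, value)
    return Override(group, rest, value)


def sensitivity_sweep(
    params: ParameterSet, overrides: Sequence[tuple[str, object]]
) -> SensitivityResult:
    """Run the baseline and an adjusted projection, and report the change
    in cumulative deficit/surplus and end-year vacancy per group.

    ``overrides`` are ``("GROUP.parameter", value)`` pairs (set-level
    parameters such as ``skill_mix`` take no group prefix).
    """
    spec = ScenarioSpec(
        name="sensitivity",
        overrides=tuple(_parse_override_path(p, v) for p, v in overrides),
    )
    base_run = project(params)
    adj_run = project(params, spec)
    return SensitivityResult(
        baseline=base_run,
        adjusted=adj_run,
        deficit_delta={
            g: adj_run.summary[g].cumulative_deficit - base_run.summary[g].cumulative_deficit
            for g in OccupationGroup
        },
        surplus_delta={
            g: adj_run.summary[g].cumulative_surplus - base_run.summary[g].cumulative_surplus
            for g in OccupationGroup
        },
        end_vacancy_delta={
            g: adj_run.summary[g].end_vacancy_rate - base_run.summary[g].end_vacancy_rate
            for g in OccupationGroup
        },
    )
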