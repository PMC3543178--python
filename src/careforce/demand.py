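"""Annual demand for new staff, decomposed into traceable components.

Each year a group needs new people to (1) replace separations, (2) staff
service growth in line with population growth and ageing, (3) cover any
additional casual requirement tied to growth, (4) backfill FTE withdrawn
by the economic-recovery shock, (5) close any excess vacancy above the
target rate, and (6) absorb the previous year's unfilled shortfall
(carryover).  Demand and supply are person counts; the underlying stocks
are FTE, and the group's average FTE converts between the two.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .parameters import (
    ConfigurationError,
    GroupParameters,
    ValidationError,
    WorkforceState,
)
from .rounding import round_half_up
from .supply import separations, shock_loss

__all__ = [
    "DemandComponents",
    "aggregate_growth_rate",
    "skill_mix_shares",
    "allocate_demand",
    "demand_step",
]


@dataclass(frozen=True)
class DemandComponents:
    """One year's demand for new staff (persons), by source.

    ``total`` is the exact sum of the components; person-rounding happens
    at reporting time, so the components may carry fractions.
    """

    replacement: float      # separations to backfill
    growth: float           # service growth converted to persons
    casual_addon: float     # extra casual need tied to growth
    shock: float            # economic-recovery FTE withdrawal, in persons
    vacancy_gap: float      # persons needed to return vacancy to target
    carryover: float        # previous year's unfilled deficit

    @property
    def total(self) -> float:
        return (
            self.replacement
            + self.growth
            + self.casual_addon
            + self.shock
            + self.vacancy_gap
            + self.carryover
        )


def aggregate_growth_rate(
    sector_rates: Mapping[str, float], sector_weights: Mapping[str, float]
) -> float:
    """All-sector growth rate: the weighted mean of sector-level rates.

    Sector rates come from converting age-group population projections
    into sector-specific impacts (acute care, community/rural, seniors
    health, public health, primary care, mental health); the weights must
    sum to 1.
    """
    if set(sector_rates) != set(sector_weights):
        raise ValidationError(
            f"sector keys differ: rates {sorted(sector_rates)} vs "
            f"weights {sorted(sector_weights)}"
        )
    if not sector_rates:
        raise ValidationError("at least one sector is required")
    if any(w < 0 for w in sector_weights.values()):
        raise ValidationError("sector weights must be non-negative")
    total_w = sum(sector_weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValidationError(f"sector weights must sum to 1, got {total_w}")
    return sum(sector_weights[s] * sector_rates[s] for s in sector_rates)


def skill_mix_shares(budgeted_fte: Sequence[float]) -> tuple[float, ...]:
    """Share of the care workforce held by each group, from budgeted FTE.

    E.g. budgeted FTE of (14653, 3060, 3039) gives shares of roughly
    70.6% / 14.7% / 14.7%.
    """
    if any(b < 0 for b in budgeted_fte):
        raise ValidationError("budgeted FTE must be non-negative")
    total = sum(budgeted_fte)
    if total == 0:
        raise ValidationError("at least one group must have budgeted FTE > 0")
    return tuple(b / total for b in budgeted_fte)


def allocate_demand(total_demand: float, shares: Sequence[float]) -> tuple[int, ...]:
    """Split a total across groups by share, in whole units that conserve
    the (rounded) total.

    Uses the largest-remainder method: floor every group's exact share,
    then hand the remaining units to the groups with the largest
    fractional parts (earlier groups win ties).
    """
    if total_demand < 0:
        raise ValidationError(f"total demand must be >= 0, got {total_demand}")
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValidationError(f"shares must sum to 1, got {sum(shares)}")
    total = round_half_up(total_demand)
    exact = [total * s for s in shares]
    floors = [int(e) for e in exact]
    remaining = total - sum(floors)
    # stable sort: largest fractional part first, index breaks ties
    order = sorted(range(len(shares)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:remaining]:
        floors[i] += 1
    return tuple(floors)


def demand_step(
    state: WorkforceState,
    params: GroupParameters,
    growth_rate: float,
    shock_rate: float,
) -> DemandComponents:
    """Demand for new staff in one year for one group.

    replacement  separations of the current head count (whole persons);
    growth       filled FTE times the growth rate, converted to persons;
    casual_addon the casual requirement applied to the growth term;
    shock        FTE withdrawn by the recovery shock, converted to persons;
    vacancy_gap  persons needed to bring vacancies down to the target rate;
    carryover    the previous year's unfilled deficit, undiminished.
    """
    if params.avg_fte <= 0:
        raise ConfigurationError("avg_fte must be positive to convert FTE to persons")
    replacement = float(separations(state.headcount, params.separation_rate))
    growth = state.filled_fte * growth_rate / params.avg_fte
    casual_addon = params.casual_requirement * growth
    shock_fte = shock_loss(state.filled_fte, shock_rate, params.shock_exposed_fraction)
    shock = shock_fte / params.avg_fte
    carryover = max(0.0, state.cumulative_deficit)
    # vacancy above target that is NOT already demanded via carryover
    # (an unmet shortfall shows up both as carryover and as unfilled FTE)
    unfilled = params.budgeted_fte - state.filled_fte
    target_unfilled = params.target_vacancy_rate * params.budgeted_fte
    vacancy_gap = (
        max(0.0, unfilled - target_unfilled - carryover * params.avg_fte)
        / params.avg_fte
    )
    return DemandComponents(
        replacement=replacement,
        growth=growth,
        casual_addon=casual_addon,
        shock=shock,
        vacancy_gap=vacancy_gap,
        carryover=carryover,
    )
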