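"""Annual supply stream and FTE/headcount measurement conventions.

Supply of new RNs and LPNs comes from the provincial graduate pipeline:
a constant annual graduating class, reduced by the historical fraction of
graduates retained in the province (Alberta's universities and colleges
are net exporters of new graduates).  HCA supply is not measured
consistently and is set to mirror demand year by year.

Also housed here are the payroll measurement conventions: average FTE
(total assigned FTE over head count, converting FTE stocks into persons)
and the active-casual proxy (the fraction of the casual payroll pool
actually working shifts).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    ConfigurationError,
    GroupParameters,
    SupplyRule,
    ValidationError,
)
from .rounding import round_half_up

__all__ = [
    "SupplyComponents",
    "MIRROR_DEMAND",
    "retained_graduates",
    "separations",
    "shock_loss",
    "average_fte",
    "active_casual",
    "annual_supply",
]

#: Sentinel returned by :func:`annual_supply` for groups whose supply is
#: defined to equal demand; the projection engine resolves it per year.
MIRROR_DEMAND = "mirror_demand"


@dataclass(frozen=True)
class SupplyComponents:
    """Annual supply for one group.

    ``new_graduate_hires`` is the number of persons the pipeline can
    deliver this year; ``capped`` records whether the retention cap binds
    (i.e. supply equals the full retained class rather than an override).
    ``mirror_demand`` marks groups whose supply copies demand.
    """

    new_graduate_hires: int
    capped: bool = False
    mirror_demand: bool = False


def retained_graduates(graduates: float, retention_rate: float) -> int:
    """Graduates hireable within the province: ``graduates * retention``,
    rounded half-up to whole persons.

    E.g. a class of 1582 retained at 70% yields 1107 hireable graduates.
    """
    if graduates < 0:
        raise ValidationError(f"graduates must be >= 0, got {graduates}")
    if not (0 <= retention_rate <= 1):
        raise ValidationError(f"retention_rate must be in [0, 1], got {retention_rate}")
    return round_half_up(graduates * retention_rate)


def separations(headcount: float, separation_rate: float) -> int:
    """Persons ending employment in a year, rounded half-up."""
    if headcount < 0:
        raise ValidationError(f"headcount must be >= 0, got {headcount}")
    if not (0 <= separation_rate <= 1):
        raise ValidationError(f"separation_rate must be in [0, 1], got {separation_rate}")
    return round_half_up(headcount * separation_rate)


def shock_loss(filled_fte: float, shock_rate: float, exposed_fraction: float) -> float:
    """FTE withdrawn by the economic-recovery shock (kept in FTE, not
    rounded: downstream conversion to persons happens in the demand step)."""
    if filled_fte < 0:
        raise ValidationError(f"filled_fte must be >= 0, got {filled_fte}")
    if not (0 <= shock_rate <= 1):
        raise ValidationError(f"shock_rate must be in [0, 1], got {shock_rate}")
    if not (0 <= exposed_fraction <= 1):
        raise ValidationError(f"exposed_fraction must be in [0, 1], got {exposed_fraction}")
    return filled_fte * shock_rate * exposed_fraction


def average_fte(total_fte: float, headcount: float) -> float:
    """Average full-time equivalency: total assigned FTE over head count.

    Used both for the regular workforce (casuals hold 0 FTE and are
    excluded from the count) and for the casual-inclusive continuing-care
    HCA proxy.
    """
    if headcount == 0:
        raise ZeroDivisionError(
            "average_fte undefined for an empty workforce (headcount = 0)"
        )
    if headcount < 0 or total_fte < 0:
        raise ValidationError("total_fte and headcount must be >= 0")
    return total_fte / headcount


def active_casual(casual_on_payroll: float, active_fraction: float) -> int:
    """Casual employees actually working shifts: payroll pool times the
    active-casual proxy, rounded half-up to persons."""
    if casual_on_payroll < 0:
        raise ValidationError(f"casual_on_payroll must be >= 0, got {casual_on_payroll}")
    if not (0 <= active_fraction <= 1):
        raise ValidationError(f"active_fraction must be in [0, 1], got {active_fraction}")
    return round_half_up(casual_on_payroll * active_fraction)


def annual_supply(params: GroupParameters, year: int) -> SupplyComponents:
    """Supply of new staff for one group in one year.

    Pipeline groups deliver their retained graduating class, a constant
    stream unless a per-year ``supply_override`` pins a different figure.
    MIRROR_DEMAND groups return a sentinel component telling the engine to
    copy that year's demand.
    """
    if params.supply_rule is SupplyRule.MIRROR_DEMAND:
        return SupplyComponents(new_graduate_hires=0, mirror_demand=True)

    override = params.supply_override_for(year)
    if override is not None:
        return SupplyComponents(new_graduate_hires=round_half_up(override), capped=False)

    if params.graduates_per_year is None or params.retention_rate is None:
        raise ConfigurationError(
            "pipeline supply requires graduates_per_year and retention_rate "
            "(or a MIRROR_DEMAND supply rule)"
        )
    hires = retained_graduates(params.graduates_per_year, params.retention_rate)
    return SupplyComponents(new_graduate_hires=hires, capped=True)
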