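"""Domain types, validation, the packaged baseline, and scenario algebra.

The model covers the three occupation groups that deliver nursing and
related care in Alberta — Registered Nurses (RN, with the small Registered
Psychiatric Nurse pool folded in), Licensed Practical Nurses (LPN) and
Health Care Aides (HCA) — and projects their supply and demand year by year
over a 2010–2020 horizon.

Everything the engine consumes lives here: per-group rate parameters,
the all-sector demand growth schedule, the economic-recovery shock
schedule, and scenario specifications (named sets of parameter overrides
applied on top of a baseline).  The published baseline parameter set is
embedded as a fixture; no external data files are required.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

__all__ = [
    "OccupationGroup",
    "SupplyRule",
    "GroupParameters",
    "GrowthSchedule",
    "ShockSchedule",
    "WorkforceState",
    "Override",
    "ScenarioSpec",
    "ParameterSet",
    "ValidationError",
    "ConfigurationError",
    "load_baseline",
    "apply_scenario",
    "published_baseline_table",
    "parameter_set_to_dict",
    "parameter_set_from_dict",
    "parameter_set_to_csv",
    "parameter_set_from_csv",
    "scenario_from_dict",
    "scenario_to_dict",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = (2010, 2020)


class ValidationError(ValueError):
    """A parameter value violates its declared range or invariant."""


class ConfigurationError(ValueError):
    """A configuration references something that does not exist."""


class OccupationGroup(str, Enum):
    """The three care-workforce groups. RPNs are folded into the RN pool."""

    RN = "RN"
    LPN = "LPN"
    HCA = "HCA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SupplyRule(str, Enum):
    """How a group's annual supply stream is produced.

    PIPELINE: retained provincial graduates (``graduates_per_year`` times
    ``retention_rate``).  MIRROR_DEMAND: supply is set equal to demand each
    year — used for HCAs, whose training pipeline is not consistently
    measured.
    """

    PIPELINE = "pipeline"
    MIRROR_DEMAND = "mirror_demand"


def _check_fraction(name: str, value: float, *, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValidationError(f"{name} must be in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class GroupParameters:
    """All per-occupation rates and stocks.

    Parameters
    ----------
    budgeted_fte:
        Funded (budgeted) positions in FTE, whether filled or vacant.
    avg_fte:
        Average full-time equivalency of employees holding an FTE;
        converts FTE stocks into head counts.  In (0, 1].
    separation_rate:
        Fraction of employees ending employment per year (turnover
        including retirement).
    retention_rate:
        Fraction of provincial graduates historically hireable within the
        province; ``None`` for groups without a graduate pipeline.
    graduates_per_year:
        Size of the annual provincial graduating class; ``None`` for
        groups without a pipeline.
    target_vacancy_rate:
        Normative fraction of funded positions expected to be unfilled.
    casual_requirement:
        Additional casual staffing need per unit of service growth
        (the model defines the lever; the baseline sets it to 0).
    casual_active_fraction:
        Fraction of the casual payroll pool actually working shifts.
    shock_exposed_fraction:
        Fraction of the group's FTE exposed to the economic-recovery
        withdrawal shock.
    supply_rule:
        PIPELINE or MIRROR_DEMAND (see :class:`SupplyRule`).
    supply_override:
        Optional externally fixed annual supply (persons/year) replacing
        the pipeline computation; either a single number or a
        ``{year: persons}`` mapping (missing years fall back to the
        pipeline).  Lets users pin supply to a published figure.
    """

    budgeted_fte: float
    avg_fte: float
    separation_rate: float
    target_vacancy_rate: float
    retention_rate: float | None = None
    graduates_per_year: float | None = None
    casual_requirement: float = 0.0
    casual_active_fraction: float = 0.526
    shock_exposed_fraction: float = 1.0
    supply_rule: SupplyRule = SupplyRule.PIPELINE
    supply_override: float | Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.budgeted_fte < 0:
            raise ValidationError(f"budgeted_fte must be >= 0, got {self.budgeted_fte}")
        if not (0 < self.avg_fte <= 1):
            raise ValidationError(f"avg_fte must be in (0, 1], got {self.avg_fte}")
        _check_fraction("separation_rate", self.separation_rate)
        _check_fraction("target_vacancy_rate", self.target_vacancy_rate)
        if self.retention_rate is not None:
            _check_fraction("retention_rate", self.retention_rate)
        if self.graduates_per_year is not None and self.graduates_per_year < 0:
            raise ValidationError(
                f"graduates_per_year must be >= 0, got {self.graduates_per_year}"
            )
        if self.casual_requirement < 0:
            raise ValidationError(
                f"casual_requirement must be >= 0, got {self.casual_requirement}"
            )
        _check_fraction("casual_active_fraction", self.casual_active_fraction)
        _check_fraction("shock_exposed_fraction", self.shock_exposed_fraction)

    def supply_override_for(self, year: int) -> float | None:
        """Resolve the supply override for ``year`` (None if not set)."""
        if self.supply_override is None:
            return None
        if isinstance(self.supply_override, Mapping):
            value = self.supply_override.get(year)
            return None if value is None else float(value)
        return float(self.supply_override)


@dataclass(frozen=True)
class GrowthSchedule:
    """Per-year all-sector growth rate of demand for the care workforce.

    The rates are age-weighted aggregates over the service sectors (acute
    care, community/rural, seniors health, public health, primary care,
    mental health); the packaged baseline carries the published aggregate
    directly.  Use :func:`careforce.demand.aggregate_growth_rate` to build
    a schedule from sector-level rates and weights.
    """

    rates: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, rate in self.rates.items():
            if rate < -1:
                raise ValidationError(f"growth rate for {year} below -100%: {rate}")
        object.__setattr__(self, "rates", dict(self.rates))

    def __getitem__(self, year: int) -> float:
        try:
            return self.rates[year]
        except KeyError:
            raise ConfigurationError(f"no growth rate defined for year {year}") from None

    def years(self) -> list[int]:
        return sorted(self.rates)


@dataclass(frozen=True)
class ShockSchedule:
    """Per-year economic-recovery withdrawal rate (fraction of FTE lost).

    When the provincial energy sector tightens, part of the nursing
    workforce reduces hours or leaves; the schedule is zero except in the
    configured onset year.
    """

    rates: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, rate in self.rates.items():
            _check_fraction(f"shock rate for {year}", rate)
        object.__setattr__(self, "rates", dict(self.rates))

    def __getitem__(self, year: int) -> float:
        return self.rates.get(year, 0.0)


@dataclass(frozen=True)
class WorkforceState:
    """The evolving stock for one group at the start of a projection year.

    ``budgeted_fte`` tracks the funded positions as they grow with demand;
    ``None`` means "use the group parameters' value" (the year-0 case).
    """

    year: int
    filled_fte: float
    headcount: float
    cumulative_deficit: float = 0.0  # carryover; negative would mean surplus
    budgeted_fte: float | None = None

    def __post_init__(self) -> None:
        if self.filled_fte < 0:
            raise ValidationError(f"filled_fte must be >= 0, got {self.filled_fte}")
        if self.headcount < 0:
            raise ValidationError(f"headcount must be >= 0, got {self.headcount}")


@dataclass(frozen=True)
class Override:
    """One scenario override: ``(group, parameter, value)``.

    ``group`` is ``None`` for set-level targets (``skill_mix``,
    ``shock_onset_year``).  ``value`` may be a scalar or a
    ``{year: value}`` mapping for time-varying overrides (supported for
    ``supply_override`` and, via the schedules, growth/shock rates).
    """

    group: OccupationGroup | None
    param: str
    value: Any

    @property
    def path(self) -> str:
        return f"{self.group.value}.{self.param}" if self.group else self.param


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides applied to a baseline."""

    name: str
    overrides: tuple[Override, ...] = ()
    description: str = ""


_GROUP_FIELDS = {f.name for f in dataclasses.fields(GroupParameters)}
_SET_LEVEL_PARAMS = {"skill_mix", "shock_onset_year", "growth", "shock"}


@dataclass(frozen=True)
class ParameterSet:
    """The full model input: three groups plus the two schedules."""

    groups: Mapping[OccupationGroup, GroupParameters]
    growth: GrowthSchedule
    shock: ShockSchedule
    horizon: tuple[int, int] = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if set(self.groups) != set(OccupationGroup):
            missing = set(OccupationGroup) - set(self.groups)
            raise ConfigurationError(f"parameter set must cover all groups; missing {missing}")
        object.__setattr__(self, "groups", dict(self.groups))

    def __getitem__(self, group: OccupationGroup | str) -> GroupParameters:
        return self.groups[OccupationGroup(group)]

    # Attribute sugar: params.RN, params.LPN, params.HCA
    def __getattr__(self, name: str) -> GroupParameters:
        try:
            return self.groups[OccupationGroup(name)]
        except (ValueError, KeyError):
            raise AttributeError(name) from None

    def total_budgeted_fte(self) -> float:
        return sum(g.budgeted_fte for g in self.groups.values())

    def years(self) -> list[int]:
        start, end = self.horizon
        return list(range(start, end + 1))


# ---------------------------------------------------------------------------
# Packaged baseline
# ---------------------------------------------------------------------------

#: Published all-sector growth rates for demand, 2010-2020.
BASELINE_GROWTH = {
    2010: 0.0256, 2011: 0.0245, 2012: 0.0240, 2013: 0.0231,
    2014: 0.0224, 2015: 0.0223, 2016: 0.0224, 2017: 0.0225,
    2018: 0.0227, 2019: 0.0223, 2020: 0.0225,
}

#: Economic-recovery withdrawal estimate: 6.63% of exposed FTE.
BASELINE_SHOCK_RATE = 0.0663
#: First projection year after the 2010 base year.
BASELINE_SHOCK_ONSET = 2011

# Average FTE of employees actually holding an FTE.  The HCA figure is the
# published continuing-care proxy (7567 FTE over 17820 heads, casuals
# included).  RN and LPN averages are estimated from the 2009 Alberta
# full/part-time mix among FTE-holders, weighting full-time at 1.0 FTE and
# part-time at 0.5 FTE: RN 26%/45% -> 0.683, LPN 29%/44% -> 0.699.
_BASELINE_AVG_FTE = {
    OccupationGroup.RN: 0.683,
    OccupationGroup.LPN: 0.699,
    OccupationGroup.HCA: 7567 / 17820,
}


def load_baseline() -> ParameterSet:
    """The published status-quo parameter set for the three groups.

    RN: 14653 budgeted FTE, 4.50% separation, 3% target vacancy, 1582
    graduates/year retained at 70%.  LPN: 3060 FTE, 5.79%, 5%, 802
    graduates at 90%.  HCA: 3039 FTE, 7.66%, 5%, supply mirrors demand.
    Growth follows the published 2010-2020 schedule; the 6.63% recovery
    shock is applied once, in 2011.
    """
    groups = {
        OccupationGroup.RN: GroupParameters(
            budgeted_fte=14653,
            avg_fte=_BASELINE_AVG_FTE[OccupationGroup.RN],
            separation_rate=0.0450,
            target_vacancy_rate=0.03,
            retention_rate=0.70,
            graduates_per_year=1582,
        ),
        OccupationGroup.LPN: GroupParameters(
            budgeted_fte=3060,
            avg_fte=_BASELINE_AVG_FTE[OccupationGroup.LPN],
            separation_rate=0.0579,
            target_vacancy_rate=0.05,
            retention_rate=0.90,
            graduates_per_year=802,
        ),
        OccupationGroup.HCA: GroupParameters(
            budgeted_fte=3039,
            avg_fte=_BASELINE_AVG_FTE[OccupationGroup.HCA],
            separation_rate=0.0766,
            target_vacancy_rate=0.05,
            supply_rule=SupplyRule.MIRROR_DEMAND,
        ),
    }
    return ParameterSet(
        groups=groups,
        growth=GrowthSchedule(BASELINE_GROWTH),
        shock=ShockSchedule({BASELINE_SHOCK_ONSET: BASELINE_SHOCK_RATE}),
        horizon=DEFAULT_HORIZON,
    )


# The published baseline projection table (status-quo scenario).  Demand and
# supply are persons; HCA supply mirrors demand.  These streams feed the
# engine's calibration mode, which re-derives deficits, carryover, vacancy
# and hiring percentages from the printed demand/supply columns.
_PUBLISHED_BASELINE = {
    # year: (rn_demand, rn_supply, lpn_demand, lpn_supply, hca_demand)
    2010: (1381, 1293, 250, 799, 1526),
    2011: (1916, 1107, 620, 799, 2669),
    2012: (3244, 1107, 632, 799, 2733),
    2013: (4481, 1107, 642, 799, 2794),
    2014: (5163, 1107, 651, 799, 2856),
    2015: (5865, 1107, 665, 799, 2923),
    2016: (6591, 1107, 680, 799, 2991),
    2017: (7342, 1107, 694, 799, 3059),
    2018: (8120, 1107, 710, 799, 3130),
    2019: (8909, 1107, 723, 799, 3194),
    2020: (9725, 1107, 738, 798, 3264),
}


def published_baseline_table() -> dict[OccupationGroup, dict[str, dict[int, int]]]:
    """Published baseline demand/supply streams (persons) per group per year.

    Returns ``{group: {"demand": {year: persons}, "supply": {...}}}``; the
    HCA entry carries only a demand stream (its supply mirrors demand).
    """
    out: dict[OccupationGroup, dict[str, dict[int, int]]] = {
        OccupationGroup.RN: {"demand": {}, "supply": {}},
        OccupationGroup.LPN: {"demand": {}, "supply": {}},
        OccupationGroup.HCA: {"demand": {}},
    }
    for year, (rn_d, rn_s, lpn_d, lpn_s, hca_d) in _PUBLISHED_BASELINE.items():
        out[OccupationGroup.RN]["demand"][year] = rn_d
        out[OccupationGroup.RN]["supply"][year] = rn_s
        out[OccupationGroup.LPN]["demand"][year] = lpn_d
        out[OccupationGroup.LPN]["supply"][year] = lpn_s
        out[OccupationGroup.HCA]["demand"][year] = hca_d
    return out


# ---------------------------------------------------------------------------
# Scenario algebra
# ---------------------------------------------------------------------------

def _apply_group_override(params: GroupParameters, ov: Override) -> GroupParameters:
    if ov.param not in _GROUP_FIELDS:
        raise ConfigurationError(
            f"unknown parameter '{ov.path}'; valid group parameters: "
            f"{sorted(_GROUP_FIELDS)}"
        )
    value = ov.value
    if ov.param == "supply_rule":
        value = SupplyRule(value)
    elif ov.param == "supply_override" and isinstance(value, Mapping):
        value = {int(y): float(v) for y, v in value.items()}
    elif ov.param != "supply_override" and isinstance(value, Mapping):
        raise ConfigurationError(
            f"parameter '{ov.path}' does not support per-year values"
        )
    # dataclasses.replace re-runs __post_init__, so range checks fire here
    return dataclasses.replace(params, **{ov.param: value})


def _apply_skill_mix(base: ParameterSet, shares: Mapping[str, float]) -> dict[OccupationGroup, GroupParameters]:
    try:
        share_map = {OccupationGroup(g): float(s) for g, s in shares.items()}
    except ValueError as exc:
        raise ConfigurationError(f"skill_mix override names an unknown group: {exc}") from None
    if set(share_map) != set(OccupationGroup):
        raise ConfigurationError("skill_mix override must give a share for every group")
    total_share = sum(share_map.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValidationError(f"skill_mix shares must sum to 1, got {total_share}")
    if any(s < 0 for s in share_map.values()):
        raise ValidationError("skill_mix shares must be non-negative")
    total_fte = base.total_budgeted_fte()
    return {
        g: dataclasses.replace(base[g], budgeted_fte=total_fte * share_map[g])
        for g in OccupationGroup
    }


def apply_scenario(base: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a new parameter set with the scenario's overrides applied.

    ``base`` is never modified; values not named by an override are
    identical to the base.  Unknown parameter paths raise
    :class:`ConfigurationError`; out-of-range values raise
    :class:`ValidationError` (both carry the offending path).
    """
    groups = dict(base.groups)
    growth = base.growth
    shock = base.shock
    for ov in scenario.overrides:
        try:
            if ov.group is not None:
                groups[ov.group] = _apply_group_override(groups[ov.group], ov)
            elif ov.param == "skill_mix":
                # reallocate the (unchanged) total budgeted FTE across groups
                reallocated = _apply_skill_mix(
                    ParameterSet(groups, growth, shock, base.horizon), ov.value
                )
                groups.update(reallocated)
            elif ov.param == "shock_onset_year":
                onset = int(ov.value)
                rate = max(shock.rates.values(), default=BASELINE_SHOCK_RATE)
                shock = ShockSchedule({onset: rate})
            elif ov.param == "growth":
                merged = dict(growth.rates)
                merged.update({int(y): float(v) for y, v in ov.value.items()})
                growth = GrowthSchedule(merged)
            elif ov.param == "shock":
                merged = dict(shock.rates)
                merged.update({int(y): float(v) for y, v in ov.value.items()})
                shock = ShockSchedule(merged)
            else:
                raise ConfigurationError(
                    f"unknown parameter '{ov.path}'; set-level parameters: "
                    f"{sorted(_SET_LEVEL_PARAMS)}"
                )
        except (ConfigurationError, ValidationError) as exc:
            raise type(exc)(f"scenario '{scenario.name}': {exc}") from None
    return ParameterSet(groups=groups, growth=growth, shock=shock, horizon=base.horizon)


# ---------------------------------------------------------------------------
# Config serialization (JSON-compatible dicts, CSV parameter tables)
# ---------------------------------------------------------------------------

def _group_to_dict(g: GroupParameters) -> dict[str, Any]:
    d = dataclasses.asdict(g)
    d["supply_rule"] = g.supply_rule.value
    if isinstance(g.supply_override, Mapping):
        d["supply_override"] = {str(y): v for y, v in g.supply_override.items()}
    return d


def _group_from_dict(d: Mapping[str, Any]) -> GroupParameters:
    kwargs = dict(d)
    unknown = set(kwargs) - _GROUP_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown group parameters: {sorted(unknown)}")
    if "supply_rule" in kwargs:
        kwargs["supply_rule"] = SupplyRule(kwargs["supply_rule"])
    so = kwargs.get("supply_override")
    if isinstance(so, Mapping):
        kwargs["supply_override"] = {int(y): float(v) for y, v in so.items()}
    return GroupParameters(**kwargs)


def parameter_set_to_dict(ps: ParameterSet) -> dict[str, Any]:
    """JSON-compatible representation; round-trips exactly through
    :func:`parameter_set_from_dict`."""
    return {
        "groups": {g.value: _group_to_dict(ps[g]) for g in OccupationGroup},
        "growth": {str(y): r for y, r in sorted(ps.growth.rates.items())},
        "shock": {str(y): r for y, r in sorted(ps.shock.rates.items())},
        "horizon": list(ps.horizon),
    }


def parameter_set_from_dict(d: Mapping[str, Any]) -> ParameterSet:
    return ParameterSet(
        groups={OccupationGroup(g): _group_from_dict(gd) for g, gd in d["groups"].items()},
        growth=GrowthSchedule({int(y): float(r) for y, r in d["growth"].items()}),
        shock=ShockSchedule({int(y): float(r) for y, r in d.get("shock", {}).items()}),
        horizon=tuple(d.get("horizon", DEFAULT_HORIZON)),  # type: ignore[arg-type]
    )


def scenario_to_dict(spec: ScenarioSpec) -> dict[str, Any]:
    return {
        "scenario_name": spec.name,
        "description": spec.description,
        "overrides": [
            {
                "group": ov.group.value if ov.group else None,
                "param": ov.param,
                "value": ov.value,
            }
            for ov in spec.overrides
        ],
    }


def scenario_from_dict(d: Mapping[str, Any]) -> ScenarioSpec:
    overrides = []
    for ov in d.get("overrides", []):
        group = ov.get("group")
        overrides.append(
            Override(
                group=OccupationGroup(group) if group else None,
                param=ov["param"],
                value=ov["value"],
            )
        )
    return ScenarioSpec(
        name=d["scenario_name"],
        description=d.get("description", ""),
        overrides=tuple(overrides),
    )


_CSV_UNITS = {
    "budgeted_fte": "FTE",
    "avg_fte": "FTE/person",
    "separation_rate": "fraction/year",
    "target_vacancy_rate": "fraction",
    "retention_rate": "fraction",
    "graduates_per_year": "persons/year",
    "casual_requirement": "fraction",
    "casual_active_fraction": "fraction",
    "shock_exposed_fraction": "fraction",
    "supply_rule": "categorical",
    "supply_override": "persons/year",
}


def parameter_set_to_csv(ps: ParameterSet, source: str = "baseline") -> str:
    """Render the parameter table as CSV with columns
    (group, parameter, value, units, source)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(["group", "parameter", "value", "units", "source"])
    for g in OccupationGroup:
        for name, value in _group_to_dict(ps[g]).items():
            if value is None:
                continue
            if isinstance(value, dict):
                value = json.dumps(value, sort_keys=True)
            writer.writerow([g.value, name, value, _CSV_UNITS.get(name, ""), source])
    for year, rate in sorted(ps.growth.rates.items()):
        writer.writerow(["ALL", f"growth[{year}]", rate, "fraction", source])
    for year, rate in sorted(ps.shock.rates.items()):
        writer.writerow(["ALL", f"shock[{year}]", rate, "fraction", source])
    writer.writerow(["ALL", "horizon_start", ps.horizon[0], "year", source])
    writer.writerow(["ALL", "horizon_end", ps.horizon[1], "year", source])
    return buf.getvalue()


def parameter_set_from_csv(text: str) -> ParameterSet:
    """Parse a parameter table written by :func:`parameter_set_to_csv`."""
    groups: dict[str, dict[str, Any]] = {g.value: {} for g in OccupationGroup}
    growth: dict[int, float] = {}
    shock: dict[int, float] = {}
    horizon = list(DEFAULT_HORIZON)
    reader = csv.DictReader(io.StringIO(text))
    for row in reader:
        group, name, raw = row["group"], row["parameter"], row["value"]
        if group == "ALL":
            if name.startswith("growth["):
                growth[int(name[7:-1])] = float(raw)
            elif name.startswith("shock["):
                shock[int(name[6:-1])] = float(raw)
            elif name == "horizon_start":
                horizon[0] = int(raw)
            elif name == "horizon_end":
                horizon[1] = int(raw)
            else:
                raise ConfigurationError(f"unknown set-level parameter '{name}'")
        else:
            if name == "supply_rule":
                groups[group][name] = raw
            elif name == "supply_override":
                groups[group][name] = (
                    json.loads(raw) if raw.startswith("{") else float(raw)
                )
            else:
                groups[group][name] = float(raw)
    return parameter_set_from_dict(
        {"groups": groups, "growth": growth, "shock": shock, "horizon": horizon}
    )
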