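"""Rendering and serialization of projection runs.

Three output forms: a human text table in the style of the published
projection tables (deficits in parentheses, whole-percent rates), RFC
4180 CSV that keeps full machine precision alongside the rounded display
columns, and JSON that round-trips a run losslessly.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Any

from .demand import DemandComponents
from .engine import GroupSummary, ProjectionRow, ProjectionRun, summarize_rows
from .parameters import OccupationGroup

__all__ = [
    "ReportOptions",
    "render_table",
    "render_csv",
    "parse_csv",
    "run_to_dict",
    "run_from_dict",
    "summarize",
    "plot_deficits",
]

_FORMATS = ("table", "csv", "json")

#: Per-group column headings, matching the published table layout.
TABLE_COLUMNS = (
    "Demand",
    "Supply",
    "Supply Surplus/ Deficit",
    "FTE Vacancy Rate",
    "% of Graduates Hired",
)


@dataclass(frozen=True)
class ReportOptions:
    """Output options: format, display rounding, optional plot and path."""

    format: str = "table"
    round_persons: bool = True
    round_percent: bool = True
    plot: bool = False
    out: str | None = None

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {self.format!r}")


def _paren(value: int) -> str:
    """Accounting style: deficits (negative values) in parentheses."""
    return f"({-value})" if value < 0 else str(value)


def _pct(value: float | None) -> str:
    return "" if value is None else f"{round(value * 100):d}%"


def render_table(run: ProjectionRun, opts: ReportOptions | None = None) -> str:
    """Render one text table per group, published-table style."""
    lines: list[str] = []
    for group in OccupationGroup:
        rows = run.rows.get(group, ())
        header = ["Year"] + [f"{group.value} {c}" if c in ("Demand", "Supply") else c
                             for c in TABLE_COLUMNS]
        table = [header]
        for r in rows:
            table.append(
                [
                    str(r.year),
                    str(r.demand),
                    str(r.supply),
                    _paren(r.surplus_deficit),
                    _pct(r.fte_vacancy_rate),
                    _pct(r.pct_graduates_hired),
                ]
            )
        widths = [max(len(row[i]) for row in table) for i in range(len(header))]
        lines.append(f"== {group.value} — scenario: {run.scenario} ==")
        for row in table:
            lines.append("  ".join(cell.rjust(w) for cell, w in zip(row, widths)))
        lines.append("")
    return "\n".join(lines)


_CSV_FIELDS = (
    "scenario",
    "year",
    "group",
    "demand",
    "supply",
    "surplus_deficit",
    "fte_vacancy_rate_pct",
    "pct_graduates_hired_pct",
    "fte_vacancy_rate",
    "pct_graduates_hired",
    "demand_exact",
    "supply_exact",
)


def render_csv(run: ProjectionRun) -> str:
    """RFC 4180 CSV: whole-person and whole-percent display columns plus
    full-precision parallel columns."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(_CSV_FIELDS)
    for group in OccupationGroup:
        for r in run.rows.get(group, ()):
            writer.writerow(
                [
                    run.scenario,
                    r.year,
                    group.value,
                    r.demand,
                    r.supply,
                    r.surplus_deficit,
                    round(r.fte_vacancy_rate * 100),
                    "" if r.pct_graduates_hired is None else round(r.pct_graduates_hired * 100),
                    repr(r.fte_vacancy_rate),
                    "" if r.pct_graduates_hired is None else repr(r.pct_graduates_hired),
                    repr(r.demand_exact),
                    repr(r.supply_exact),
                ]
            )
    return buf.getvalue()


def parse_csv(text: str) -> ProjectionRun:
    """Parse CSV written by :func:`render_csv` back into a run.

    The demand-component breakdown is not carried by CSV (use JSON for a
    lossless round trip of components); every other field is exact.
    """
    rows: dict[OccupationGroup, list[ProjectionRow]] = {g: [] for g in OccupationGroup}
    scenario = "baseline"
    for rec in csv.DictReader(io.StringIO(text)):
        scenario = rec["scenario"]
        group = OccupationGroup(rec["group"])
        rows[group].append(
            ProjectionRow(
                year=int(rec["year"]),
                group=group,
                demand=int(rec["demand"]),
                supply=int(rec["supply"]),
                surplus_deficit=int(rec["surplus_deficit"]),
                fte_vacancy_rate=float(rec["fte_vacancy_rate"]),
                pct_graduates_hired=(
                    None if rec["pct_graduates_hired"] == "" else float(rec["pct_graduates_hired"])
                ),
                demand_exact=float(rec["demand_exact"]),
                supply_exact=float(rec["supply_exact"]),
            )
        )
    years = [r.year for rs in rows.values() for r in rs]
    horizon = (min(years), max(years)) if years else (0, -1)
    return ProjectionRun(scenario=scenario, horizon=horizon, rows=rows)


def run_to_dict(run: ProjectionRun) -> dict[str, Any]:
    """Lossless JSON-compatible representation of a run."""
    return {
        "scenario": run.scenario,
        "horizon": list(run.horizon),
        "rows": {
            g.value: [
                {
                    **{
                        k: v
                        for k, v in dataclasses.asdict(r).items()
                        if k not in ("group", "components")
                    },
                    "components": (
                        None if r.components is None else dataclasses.asdict(r.components)
                    ),
                }
                for r in rows
            ]
            for g, rows in run.rows.items()
        },
        "summary": {
            g.value: {
                "cumulative_deficit": s.cumulative_deficit,
                "cumulative_surplus": s.cumulative_surplus,
                "end_vacancy_rate": s.end_vacancy_rate,
                "cap_binding_years": list(s.cap_binding_years),
            }
            for g, s in run.summary.items()
        },
    }


def run_from_dict(d: Mapping[str, Any]) -> ProjectionRun:
    rows: dict[OccupationGroup, list[ProjectionRow]] = {}
    for gname, rlist in d["rows"].items():
        group = OccupationGroup(gname)
        rows[group] = [
            ProjectionRow(
                group=group,
                components=(
                    None if r.get("components") is None else DemandComponents(**r["components"])
                ),
                **{k: v for k, v in r.items() if k != "components"},
            )
            for r in rlist
        ]
    summary = {
        OccupationGroup(g): GroupSummary(
            cumulative_deficit=s["cumulative_deficit"],
            cumulative_surplus=s["cumulative_surplus"],
            end_vacancy_rate=s["end_vacancy_rate"],
            cap_binding_years=tuple(s["cap_binding_years"]),
        )
        for g, s in d.get("summary", {}).items()
    }
    return ProjectionRun(
        scenario=d["scenario"],
        horizon=tuple(d["horizon"]),  # type: ignore[arg-type]
        rows=rows,
        summary=summary,
    )


def render_json(run: ProjectionRun) -> str:
    return json.dumps(run_to_dict(run), indent=2, sort_keys=True)


def summarize(run: ProjectionRun) -> str:
    """Headline text summary; every figure is recomputed from the rows."""
    lines = [f"Scenario: {run.scenario} ({run.horizon[0]}-{run.horizon[1]})"]
    any_shortfall = False
    for group in OccupationGroup:
        rows = run.rows.get(group, ())
        s = summarize_rows(rows)
        if s.cumulative_deficit > 0:
            any_shortfall = True
            lines.append(
                f"  {group.value}: cumulative deficit of {s.cumulative_deficit} by "
                f"{run.horizon[1]}; vacancy rate reaches {round(s.end_vacancy_rate * 100)}%"
            )
        elif rows:
            lines.append(
                f"  {group.value}: cumulative surplus of {s.cumulative_surplus}; "
                f"end vacancy rate {round(s.end_vacancy_rate * 100)}%"
            )
        if s.cap_binding_years:
            span = f"{s.cap_binding_years[0]}-{s.cap_binding_years[-1]}"
            lines.append(
                f"    hiring cap binds in {len(s.cap_binding_years)} year(s) ({span})"
            )
    if not any_shortfall:
        lines.append("  no shortfall projected")
    return "\n".join(lines)


def plot_deficits(runs: Sequence[ProjectionRun], path: str) -> None:
    """Plot surplus/deficit trajectories per group (one panel each).

    Requires matplotlib; plots are a convenience and nothing else in the
    package depends on them.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4), sharex=True)
    for ax, group in zip(axes, OccupationGroup):
        for run in runs:
            rows = run.rows.get(group, ())
            ax.plot(
                [r.year for r in rows],
                [r.surplus_deficit for r in rows],
                label=run.scenario,
            )
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(group.value)
        ax.set_xlabel("Year")
    axes[0].set_ylabel("Supply surplus / deficit (persons)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
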