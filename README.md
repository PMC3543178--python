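# careforce

A deterministic stock-and-flow projection engine for planning the *care
workforce* — Registered Nurses (RN, including the small Registered
Psychiatric Nurse pool), Licensed Practical Nurses (LPN) and Health Care
Aides (HCA) — over a 2010–2020 horizon, in the setting of a single
province-wide provider (Alberta). It is written for health-workforce
planners and analysts who need a transparent, scriptable alternative to
spreadsheet/dashboard models: every assumption is an explicit parameter,
every scenario is a named set of overrides, and every output cell is
recomputable.

## The model

For each occupation group, employment evolves by a yearly recursion

```
E(t+1) − E(t) = Demanded(t) − Supplied(t)
```

where the demand for new staff (persons) decomposes additively into

| component   | definition                                                        |
|-------------|-------------------------------------------------------------------|
| replacement | φ·H(t) — separations (turnover incl. retirement) to backfill      |
| growth      | E(t)·ΔPop(t) / AvgFTE — service growth from population growth/aging |
| casual      | γ × growth — additional casual requirement                        |
| shock       | ε(t)·E(t)·exposed / AvgFTE — economic-recovery FTE withdrawal     |
| vacancy gap | excess vacancy above the target rate α, net of carryover          |
| carryover   | last year's unfilled shortfall, undiminished                      |

with `E` filled FTE, `H = E/AvgFTE` headcount, `φ` the separation rate,
`ΔPop` the all-sector age-weighted growth rate, `α` the target vacancy
rate, and `ε` the recovery shock (6.63 % of exposed FTE). Supply is the
retained provincial graduating class (`θ · NewGraduates`: 1582 RN
graduates retained at 70 % → 1107/yr; 802 LPN at 90 % → 722/yr); HCA
supply is defined to mirror demand. Shortfalls carry over into next
year's demand; surpluses are not banked. Budgeted FTE grows with
`(1 + ΔPop)` each year.

The packaged baseline holds the published status-quo parameters
(budgeted FTE 14653/3060/3039; separation rates 4.50 %/5.79 %/7.66 %;
vacancy targets 3 %/5 %/5 %; growth 2.56 %→2.25 %). A *calibration mode*
lets you pin demand and/or supply to externally given yearly streams
(e.g. a published projection table) and have the engine recompute all
downstream accounting — deficits, carryover, vacancy, hiring shares.

## Worked example

```python
import careforce as cf

base = cf.load_baseline()
streams = cf.published_baseline_table()
run = cf.project(
    base,
    demand_streams={g: s["demand"] for g, s in streams.items()},
    supply_streams={g: s["supply"] for g, s in streams.items() if "supply" in s},
)
print(cf.summarize(run))
```

prints

```
Scenario: baseline (2010-2020)
  RN: cumulative deficit of 8618 by 2020; vacancy rate reaches 35%
    hiring cap binds in 11 year(s) (2010-2020)
  LPN: cumulative surplus of 1783; end vacancy rate 5%
  HCA: cumulative surplus of 0; end vacancy rate 5%
```

Under status-quo policy the RN pipeline (1107 hireable graduates a year)
falls further behind demand every year; by 2020 the carried-over
shortfall reaches 8618 RNs. LPN supply exceeds demand throughout (the
yearly surpluses sum to 1783 but are not banked), and HCA supply mirrors
demand by construction. The same run as a table (`cf.render_table(run)`):

```
== RN — scenario: baseline ==
Year  RN Demand  RN Supply  Supply Surplus/ Deficit  FTE Vacancy Rate  % of Graduates Hired
2010       1381       1293                     (88)                3%                   70%
2011       1916       1107                    (809)                7%                   70%
2012       3244       1107                   (2137)               12%                   70%
...
```

From the shell, the same engine drives a CLI:

```
careforce project --scenario baseline --format csv --out runs/
careforce scenarios --all
careforce sensitivity --param RN.separation_rate --values 0.0343
careforce params --format csv
```

The six packaged policy scenarios (status quo, aged-care skill-mix
shift, full-time work, retirement impact, LPN expansion, HCA expansion)
are in `cf.packaged_scenarios()`; user scenarios are JSON files of
`{group, param, value}` overrides validated against the parameter schema.

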