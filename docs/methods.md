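# Methods

## Model

`careforce` implements a deterministic yearly stock-and-flow recursion for
three occupation groups (RN, LPN, HCA). The state per group is (filled
FTE `E`, headcount `H = E/AvgFTE`, budgeted FTE `B`, carried-over
shortfall `C`). One projection step computes:

1. **Demand** (persons) as an additive decomposition:
   - replacement `= round(φ·H)` — separations to backfill;
   - growth `= E·ΔPop / AvgFTE` — service demand grows with the
     all-sector age-weighted population growth rate;
   - casual add-on `= γ ×` growth;
   - shock `= ε·E·exposed / AvgFTE` — FTE withdrawn when the energy
     labour market tightens;
   - vacancy gap `= max(0, (B − E) − α·B − C·AvgFTE)/AvgFTE` — persons
     needed to return the vacancy rate to its target `α`, *net of* the
     carried shortfall (an unmet shortfall already appears both as
     carryover and as unfilled FTE; subtracting `C·AvgFTE` avoids
     counting it twice, which would make the recursion diverge);
   - carryover `= C` — last year's unfilled demand, undiminished.
2. **Supply** (persons): the retained graduating class
   `round(θ · NewGraduates)`, a constant annual stream unless a per-year
   override pins another figure. HCA supply is set equal to demand
   (MIRROR_DEMAND): the HCA training pipeline is not consistently
   measured, so the group never runs a deficit by construction.
3. **Update**: `C' = max(0, demand − supply)`;
   `E' = E + min(supply, demand)·AvgFTE − replacement·AvgFTE − shock_FTE`
   (hires cannot exceed demand; surpluses are not banked as future
   supply); `B' = B·(1 + ΔPop)`.

The recursion is deterministic — identical inputs give bit-identical
runs — and the accounting identity for `E'` is asserted to 1e-6 in the
test suite.

### Rounding

Person counts round half-up (`floor(x + 0.5)`; 721.8 → 722, 76.6 → 77)
at operation boundaries and at row-reporting time; the state fold itself
keeps floating point to avoid drift. Percentages render as whole
percent; CSV output carries full-precision parallel columns.

### Vacancy-rate reporting

The published projection table's vacancy column cannot be reconstructed
exactly (its denominator is not stated). The package reports, per group,
`(α·B + C'·AvgFTE) / B` clipped to [0, 1]: the target allowance plus the
FTE footprint of the unmet shortfall over budgeted FTE. This equals the
target rate exactly whenever supply covers demand, and rises with the
deficit (baseline RN: 3 % in 2010 growing past 20 % by 2020). The level,
not the direction, is calibration-dependent.

## Parameters

| parameter | meaning | RN | LPN | HCA | units |
|---|---|---|---|---|---|
| budgeted_fte | funded positions | 14653 | 3060 | 3039 | FTE |
| avg_fte | mean FTE per FTE-holder | 0.683 | 0.699 | 0.4246 | FTE/person |
| separation_rate φ | leavers per year | 0.0450 | 0.0579 | 0.0766 | fraction/yr |
| target_vacancy_rate α | normative unfilled share | 0.03 | 0.05 | 0.05 | fraction |
| retention_rate θ | graduates hireable in-province | 0.70 | 0.90 | — | fraction |
| graduates_per_year | provincial class size | 1582 | 802 | — | persons/yr |
| casual_requirement γ | casual need per unit growth | 0 | 0 | 0 | fraction |
| casual_active_fraction | casual pool working shifts | 0.526 | 0.526 | 0.526 | fraction |
| shock_exposed_fraction | FTE exposed to the shock | 1.0 | 1.0 | 1.0 | fraction |

Growth rates: 2.56, 2.45, 2.40, 2.31, 2.24, 2.23, 2.24, 2.25, 2.27,
2.23, 2.25 % for 2010–2020. Recovery shock: 6.63 % of exposed FTE,
applied once in 2011 (the first projection year; the onset is
configurable via `shock_onset_year` — the published table's demand jump
between 2011 and 2012 is consistent with a 2012 onset).

Choices where the published record is silent:

- **avg_fte (RN/LPN)**: no value is printed. Estimated from the 2009
  Alberta full/part-time mix among FTE-holders, weighting full-time at
  1.0 and part-time at 0.5 FTE: RN (0.26·1 + 0.45·0.5)/0.71 = 0.683, LPN
  (0.29·1 + 0.44·0.5)/0.73 = 0.699. HCA uses the printed
  continuing-care proxy 7567/17820 = 0.4246 (casuals included).
- **γ** defaults to 0 (the lever exists; no rate is published).
- **shock_exposed_fraction** defaults to 1.0; the regional
  (Calgary/Edmonton/Fort McMurray) share of FTE is not published, so
  regional exposure is a single configurable fraction.
- **LPN supply**: the published table shows 799/yr while 802 × 90 % =
  722. The fixture computes 722; `supply_override` (scalar or per-year)
  selects the published convention where needed. The same mechanism
  covers the published RN 2010 supply of 1293 (unexplained; not guessed).
- **Scenario magnitudes**: the six packaged scenarios encode the policy
  directions (skill-mix shifts, higher average FTE, higher separation)
  with package-default magnitudes — five- or ten-point share shifts,
  +0.1 average FTE, +1 percentage point separation — since no figures
  are published; every value is overridable in a scenario config.

## Calibration mode

`project(..., demand_streams=, supply_streams=)` pins either side of the
ledger to externally fixed yearly person streams per group. The engine
then recomputes only the downstream accounting (deficit, carryover,
vacancy, % of graduates hired, cumulative totals). This is how the
package reproduces the published baseline table's arithmetic exactly —
e.g. the 2012 RN shortfall 3244 − 1107 = 2137, the 2020 cumulative RN
deficit 9725 − 1107 = 8618, and the cumulative LPN surplus 1783 (the
published text says 1,784, computed from unrounded cells) — without
pretending the free-running demand reconstruction matches the published
demand column cell-for-cell, which the published record underdetermines
(the demand equation as printed is garbled, and the shock timing and
vacancy denominator are unstated). The free-running baseline is
qualitatively faithful: an RN deficit growing to ~5000–9000 depending on
shock timing, a persistent LPN surplus, and RN vacancy rising from 3 %
to >20 % (22 % in 2020 under the default settings).

## What the tests show — and don't

Tests cover: exact reproduction of every published arithmetic quantity
via the fixture and calibration mode; the recursion's invariants
(accounting identity ±1e-6, zero-rate fixed point, carryover zero when
supply covers demand, determinism); monotonicity of deficits in
separation rate and growth and their reduction with graduates and
retention; a three-year hand-unrolled oracle written independently of
the engine; and the published direction of the turnover sensitivity
(lower separation rates shrink the RN deficit and raise the LPN surplus
every year — the published magnitude, ≈8500 → ≈5500, depends on the
unpublished demand calibration and is checked for direction only).

They do not show that the free-running demand reconstruction matches the
published demand column cell-for-cell, nor anything about real payroll
data: parameters are consumed as given, not estimated, and
inter-professional substitution, inter-provincial recruitment flows, and
cost assessment are out of scope.

## Numerical notes and edge cases

- All rates validate into [0, 1] at construction; violations raise
  `ValidationError`, unknown parameter paths `ConfigurationError`.
- `average_fte` with zero headcount raises `ZeroDivisionError` with an
  explicit message; `vacancy_rate` requires a positive denominator and
  clips to [0, 1].
- `allocate_demand` uses largest-remainder rounding (floor all, hand
  leftover units to the largest fractional parts, earlier groups winning
  ties) so group allocations conserve the total exactly.
- Filled FTE is floored at 0; an empty horizon yields an empty run.
- Problem sizes are tiny (11 years × 3 groups of scalar arithmetic), so
  the whole suite and the acceptance script run in seconds.
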