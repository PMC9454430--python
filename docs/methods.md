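# Methods

## Scope and model structure

`pigcost` implements a deterministic enterprise-budget model for a
full-cycle swine farm, resolved to the weekly batch of market pigs. It
is an accounting model, not a simulation: given a farm description it
evaluates a fixed set of arithmetic rules and reports a cost ledger and
an indicator suite. There is no stochastic herd dynamics, no parity
structure or replacement scheduling, no price forecasting, and no
tax-law computation (statutory amounts such as ICMS, Funrural, GTA and
ITR are user-entered annual figures).

## Herd flow

The weekly sow group is `GS = N · ppa · txparto / φ` with `φ = 365/7`.
Note the convention: GS scales **down** with a lower farrowing rate. A
demographic argument could instead divide by the farrowing rate (more
services are needed per farrowing); the model deliberately keeps the
multiplicative form, which reads GS as the expected weekly *farrowing*
group driving input consumption. Users who prefer the service-group
reading can enter `txparto = 1` and fold the rate into `ppa`.

The piglet cohort `GS · Nnv` passes through the grow-out phases **in
the order listed**, each phase retaining `1 − Txmort`. This is a
sequential survival chain: the farrowing-room survivors enter the
nursery, and so on. Summing independently discounted cohorts instead
would double-count losses. Head counts stay fractional everywhere — the
weekly group is a calendar average, not a census, and rounding would
bias every per-head figure downstream.

Breeding-stock rows (dams in gestation/lactation, gilts, boars) carry
user-entered standing head counts. They are consuming populations for
feed and health costing but never enter the market-pig chain; GS drives
only insemination-linked inputs and the piglet cohort. Culls are a
steady weekly stream: `head_on_farm · annual_rate / φ · cull_weight` kg
per sex, sold at the cull price alongside the batch.

## Cost conventions

* **Time basis.** Monthly items (salaries, electricity, phone/internet,
  fuel, consumables) divide by `ω = 4.345` weeks/month — the printed
  managerial constant, stored literally, not recomputed. Annual items
  (depreciation, maintenance, fixed and variable taxes, capital and
  land remuneration, culling) divide by `φ = 365/7`. The exactness of
  both conversions (weekly × φ = annual, weekly × ω = monthly) is a
  tested invariant.
* **Feed.** A diet line charges `price · days_per_cycle · kg_per_day ·
  head`. For grow-out phases the natural entry is the whole phase
  length in days (the cohort's full feed bill lands on its batch); for
  standing breeding rows, a 7-day cycle gives the weekly bill.
* **Reproduction.** All scenario lines (on-farm semen production,
  purchased doses, or both) are `price × units per female × GS`; lab
  *equipment* belongs in the asset register, not here.
* **Labor is fixed.** Headcount does not move with one more pig sold,
  so salaries sit in group B; the schema does not offer a variable
  labor option.
* **Depreciation** is straight-line, `(value − residual)/useful life`,
  with manager-chosen life and residual fraction — including for
  biological assets (a sow depreciates from purchase price to cull
  value over her productive life). No tax-code schedules.
* **Apportionment.** Utilities and phone/internet carry one shared
  swine-activity fraction; each fuel line carries its own (default 1).
  The share applies before the weekly conversion.
* **Insurance** is a per-batch rate on the capital invested in the
  batch (`head × weight × market price`), applied once — no
  annualization.
* **Opportunity costs** are simple annual prorations: rate × asset
  value / φ (fixed capital), rate × raising subtotal / φ (working
  capital), area × lease price / φ (land). No compounding. The rates
  are always user inputs (the Selic reference rate is a typical
  choice). Note a dimensional quirk of the working-capital rule as
  defined: it remunerates *one week's* raising expenditure for one
  week, so it is small relative to the fixed-capital term; it is
  implemented as defined and flagged here for users.
* **Leveling point** uses market-pig revenue only (`CT / (price ×
  weight)`); cull revenue is excluded from the break-even denominator.
* **Producer income** `L + CO + β`: the opportunity cost of own capital
  and land is income to the producer, and β (family-labor remuneration,
  per week) enters income only — never the cost ledger.

## Numerical choices

All arithmetic is double precision with no internal rounding; two-
decimal rounding happens only in the plain-text report. CSV and JSON
reports, and CSV register files, are written so floats round-trip
exactly (`%.17g` on write, round-trip parsing on read). Ratio
indicators with zero denominators raise `UndefinedIndicatorError`
rather than returning infinity; the end-to-end engine reports them as
undefined (`None` / "n/a") for degenerate farms with zero cost or zero
market price. Validation is two-layered: negative money or quantities
fail schema parsing with the offending key path; rate-range and
cross-reference problems are collected as findings (errors/warnings) so
a whole config can be reviewed at once.

## Synthetic farms

The generator emulates plausible Brazilian full-cycle farms at three
sow-herd sizes (50–200, 200–1000, 1000–5000). Every parameter is a
uniform draw within documented bounds (`pigcost.synth.BOUNDS`) chosen
as realistic magnitudes — e.g. 2.2–2.5 farrowings/sow-year, 11–15 born
alive, 105–130 kg finished weight, feed at R$1.2–2.6/kg, pigs at
R$5–8/kg live — and yielding production costs around R$5–6.5/kg with
benefit-cost ratios straddling 1. The bounds are test scaffolding, not
data from any real farm. Each register draws from its own named random
stream, so adding a register never shifts the other draws for a fixed
seed, and a (seed, size) pair reproduces a byte-identical config.

What the generator does **not** emulate: correlated prices (feed and
pig prices co-move in reality), seasonal and batch-to-batch
variability, heterogeneous diets within a phase, or empty registers.
Tests passing on these farms therefore demonstrate the arithmetic and
its invariants — additivity, homogeneity in prices, monotonicity,
unit-conversion exactness, equivalence with an independently written
flat-ledger oracle — not the calibration of any real enterprise.

## Problem sizes used in tests

The invariant suites run the full engine over 100 generated farms
(seeds 0–99, sizes cycling small/medium/large) plus 200 single-price
perturbations; the whole suite completes in a few seconds. The
acceptance script reports one seeded medium farm end to end.

## Known limitations

Single-batch, steady-state view: no multi-week time series, discounting
or NPV. One currency label, no conversion. The working-capital
remuneration convention above. Mixed enterprises are handled only
through the apportionment shares.
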