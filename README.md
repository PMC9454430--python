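# pigcost

A weekly-batch production cost and profitability model for **full-cycle
swine farms** — operations that breed, farrow, wean and finish market
pigs on one site. It is written for farm economists, technical advisers
and producers who need a standard, auditable way to answer the question
most farms cannot: *what does one market hog actually cost to produce?*

## The model

The accounting unit is the **weekly batch** *l*: the cohort of market
pigs sold in one week, carrying all the costs of the production cycle
that produced it. Costs are allocated in the classic enterprise-budget
hierarchy:

```
A  Variable costs            CV   (feed, health, reproduction, consumables,
                                   transport & insurance, variable taxes)
B  Fixed operating costs     CFOP (labor, utilities, fuel, straight-line
                                   depreciation, maintenance, fixed taxes)
C  Operating cost            COP = CV + CFOP
D  Capital & land remuneration CO (opportunity cost of fixed capital,
                                   working capital and land)
E  Total cost                CT  = COP + CO
```

Production flow starts from the **weekly sow group**

```
GS = N · ppa · txparto / φ ,      φ = 365/7 weeks per year
```

(N sows in production, ppa farrowings per sow-year, txparto the
farrowing rate). The piglet cohort `GS · Nnv` is chained through the
grow-out phases, each removing its mortality fraction, leaving the
finished head count `Ntl` and the batch weight `θ = Ntl · kgcab`.
Monthly inputs convert to the week by dividing by ω = 4.345 weeks per
month, annual inputs by φ.

On top of the ledger the engine reports: cost per head, per **arroba**
(18.75 kg) and per kg; weekly revenue (batch plus breeding-stock culls);
profit `L = Rs − CT`; the break-even **leveling point**
`PN = CT / (Pvc · kgcab)` in head; the benefit-cost ratio `RBC = Rs/CT`;
return on investment `ROI = RBC − 1`; and the producer's total income
`RTs = L + CO + β` (the opportunity costs are income to the owner of the
factors; β remunerates family labor and never enters the cost ledger).

## Worked example

Generate a small synthetic farm (192 sows for this seed) and compute its
weekly batch:

```bash
pigcost synth --seed 7 --size small --out farm.yaml
pigcost validate --config farm.yaml
pigcost compute --config farm.yaml
```

The report prints the full ledger (group A starts with the feed lines —
by far the largest cost block on any pig farm) and ends with:

```
ECONOMIC INDICATORS
  operating cost (A + B), per week                               75,118.81
  total cost (A + B + D), per week                               76,969.16
  total cost per finished head                                      812.24
  total cost per arroba (18.75 kg)                                  121.91
  total cost per kg live weight                                       6.50
  weekly revenue (batch + culls)                                 63,024.71
  weekly profit                                                 -13,944.45
  leveling point, head                                              117.88
  benefit-cost ratio                                                  0.82
  return on investment (fraction)                                  -18.12%
  producer total weekly income                                  -10,217.46
```

Reading it: this farm produces at R$6.50/kg but the drawn market price
pays only R$5.32/kg, so the batch loses R$13,944 per week (RBC 0.82:
each real spent returns 82 centavos). It would break even selling
117.9 head per week at current costs and prices. The producer's own
income is less negative than the profit because the capital and land
remuneration inside the total cost flows back to the owner.

Configurations are one YAML file; the tabular registers (diets, health,
labor, assets, ...) can be inline or sidecar CSV files
(`pigcost synth --registers csv`). `pigcost compute --out report.csv
--format csv|json|text` writes machine-readable reports that round-trip
at full precision.

As a library:

```python
from pigcost import compute_batch, load_farm_config

cfg = load_farm_config("farm.yaml")
result = compute_batch(cfg)
print(result.report.cost_per_kg, result.report.benefit_cost_ratio)
```

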