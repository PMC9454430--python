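"""Hierarchical cost ledger: groups A-E with line items and subtotals.

The ledger mirrors the standard enterprise-budget allocation:

* **A — Variable costs**: animal-costing lines (feed, health,
  reproduction, consumer goods, with the raising subtotal), transport
  and insurance, variable taxes and fees.
* **B — Fixed operating costs**: labor; phone/internet, electricity and
  fuel; depreciation; maintenance; fixed taxes and fees.
* **C — Operating cost** = A + B.
* **D — Capital and land remuneration** (opportunity costs).
* **E — Total cost** = C + D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .fixed import FixedCosts
from .opportunity import OpportunityCosts
from .variable import VariableCosts

Level = Literal["item", "subtotal", "group", "total"]


@dataclass(frozen=True)
class LedgerLine:
    group: str  # "A".."E"
    section: str
    label: str
    amount: float
    level: Level = "item"


@dataclass(frozen=True)
class CostLedger:
    lines: list[LedgerLine] = field(default_factory=list)
    variable_total: float = 0.0  # group A
    fixed_total: float = 0.0  # group B
    opportunity_total: float = 0.0  # group D

    @property
    def operating_cost(self) -> float:
        return self.variable_total + self.fixed_total

    @property
    def total_cost(self) -> float:
        return self.operating_cost + self.opportunity_total

    def group_lines(self, group: str) -> list[LedgerLine]:
        return [l for l in self.lines if l.group == group]

    def item_sum(self) -> float:
        """Sum of the leaf line items of groups A, B and D — must equal
        the total cost exactly (additivity oracle)."""
        return sum(
            l.amount
            for l in self.lines
            if l.level == "item" and l.group in ("A", "B", "D")
        )


def build_ledger(
    var: VariableCosts, fx: FixedCosts, opp: OpportunityCosts
) -> CostLedger:
    """Lay out the computed cost groups as a flat, ordered ledger."""
    lines: list[LedgerLine] = []

    def add(group: str, section: str, label: str, amount: float,
            level: Level = "item") -> None:
        lines.append(LedgerLine(group, section, label, amount, level))

    # --- A: variable costs -------------------------------------------------
    for cl in var.feed_lines:
        add("A", "feed", cl.label, cl.amount)
    add("A", "feed", "feed subtotal", var.feed_total, "subtotal")
    for cl in var.health_lines:
        add("A", "health", cl.label, cl.amount)
    add("A", "health", "health subtotal", var.health_total, "subtotal")
    for cl in var.repro_lines:
        add("A", "reproduction", cl.label, cl.amount)
    add("A", "reproduction", "reproduction subtotal", var.repro_total,
        "subtotal")
    for cl in var.goods_lines:
        add("A", "consumer goods", cl.label, cl.amount)
    add("A", "consumer goods", "consumer goods subtotal", var.goods_total,
        "subtotal")
    add("A", "raising", "raising subtotal", var.raising_subtotal, "subtotal")
    add("A", "transport/insurance", "batch transport", var.transport)
    add("A", "transport/insurance", "batch insurance", var.insurance)
    add("A", "transport/insurance", "transport and insurance subtotal",
        var.transport_insurance_subtotal, "subtotal")
    add("A", "variable taxes", "variable taxes and fees (weekly)",
        var.financial)
    add("A", "total", "A - variable costs", var.total, "group")

    # --- B: fixed operating costs ------------------------------------------
    for cl in fx.labor_lines:
        add("B", "labor", cl.label, cl.amount)
    add("B", "labor", "labor subtotal", fx.labor_total, "subtotal")
    add("B", "utilities", "electricity", fx.electricity)
    add("B", "utilities", "telephone and internet", fx.phone_internet)
    for cl in fx.fuel_lines:
        add("B", "fuel", cl.label, cl.amount)
    add("B", "fuel", "fuel subtotal", fx.fuel_total, "subtotal")
    for cl in fx.depreciation_lines:
        add("B", "depreciation", cl.label, cl.amount)
    add("B", "depreciation", "depreciation subtotal", fx.depreciation_total,
        "subtotal")
    for cl in fx.maintenance_lines:
        add("B", "maintenance", cl.label, cl.amount)
    add("B", "maintenance", "maintenance subtotal", fx.maintenance_total,
        "subtotal")
    add("B", "fixed taxes", "fixed taxes and fees (weekly)", fx.financial)
    add("B", "total", "B - fixed operating costs", fx.total, "group")

    # --- C: operating cost -------------------------------------------------
    add("C", "total", "C - operating cost (A + B)", var.total + fx.total,
        "group")

    # --- D: opportunity ----------------------------------------------------
    add("D", "opportunity", "remuneration on fixed capital",
        opp.fixed_capital)
    add("D", "opportunity", "remuneration on working capital",
        opp.working_capital)
    add("D", "opportunity", "opportunity cost of land lease", opp.land)
    add("D", "total", "D - capital and land remuneration", opp.total, "group")

    # --- E: total ----------------------------------------------------------
    add("E", "total", "E - total cost (C + D)",
        var.total + fx.total + opp.total, "total")

    return CostLedger(
        lines=lines,
        variable_total=var.total,
        fixed_total=fx.total,
        opportunity_total=opp.total,
    )
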