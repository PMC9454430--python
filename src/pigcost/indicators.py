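"""Total cost, unit costs, revenue and the profitability suite.

The operating cost is variable + fixed operating (groups A + B); adding
the opportunity cost (group D) gives the total economic cost of the
weekly batch. Unit costs are per head, per arroba (18.75 kg) and per
kilogram. Revenue values the batch and the weekly culls at market
prices; from revenue and total cost follow profit, the leveling
(break-even) point in head, the benefit-cost ratio, the return on
investment, and the producer's total income (profit plus the
opportunity costs — which are income to the owner of the factors — plus
the family-labor remuneration).

Ratios are stored as fractions; rendering to percentages happens only
in the report writer. Indicators whose denominator is zero raise
:class:`~pigcost.errors.UndefinedIndicatorError` rather than returning
infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import UndefinedIndicatorError
from .models import MarketParams
from .timebase import TIME_BASIS, TimeBasis


def total_cost(
    variable: float, fixed_operating: float, opportunity: float
) -> tuple[float, float]:
    """Operating cost (A + B) and total cost (A + B + D).

    Returns (operating_cost, total_cost).
    """
    operating = variable + fixed_operating
    return operating, operating + opportunity


def unit_costs(
    ct: float,
    finished_head: float,
    weight_kg: float,
    tb: TimeBasis = TIME_BASIS,
) -> tuple[float, float, float]:
    """Cost per head, per arroba and per kilogram of the batch.

    The per-arroba cost is the total cost over the batch weight
    expressed in arrobas, hence always 18.75x the per-kg cost.
    Returns (per_head, per_arroba, per_kg).
    """
    if ct == 0.0:
        return 0.0, 0.0, 0.0
    if finished_head <= 0 or weight_kg <= 0:
        raise UndefinedIndicatorError(
            "unit costs undefined: no finished head (or zero weight) "
            "with nonzero total cost"
        )
    per_head = ct / finished_head
    per_kg = ct / (finished_head * weight_kg)
    per_arroba = ct / ((finished_head * weight_kg) / tb.arroba_kg)
    return per_head, per_arroba, per_kg


def revenue(
    batch_weight_kg: float,
    cull_weight_kg: dict[str, float],
    market: MarketParams,
    finished_head: float,
) -> tuple[float, float, float]:
    """Weekly revenue: market pigs by live kg plus culls by live kg.

    Returns (total, per_head, per_kg); the averages are over market
    pigs, the basis on which producers quote them.
    """
    total = batch_weight_kg * market.pig_price_kg + sum(
        kg * market.cull_price_kg for kg in cull_weight_kg.values()
    )
    if total == 0.0:
        return 0.0, 0.0, 0.0
    if finished_head <= 0 or batch_weight_kg <= 0:
        raise UndefinedIndicatorError(
            "average revenue undefined: nonzero revenue with empty batch"
        )
    return total, total / finished_head, total / batch_weight_kg


def profitability(
    rs: float, ct: float, pig_price_kg: float, weight_kg: float
) -> tuple[float, float, float, float]:
    """Profit, leveling point, benefit-cost ratio and ROI.

    Profit L = revenue - total cost. The leveling point is the head
    count whose sale (at market price and finished weight, culls
    excluded) covers the total cost. RBC = revenue per unit cost;
    ROI = profit per unit cost = RBC - 1.

    Returns (profit, leveling_point_head, benefit_cost_ratio, roi).
    """
    if ct <= 0.0:
        raise UndefinedIndicatorError(
            "ratio indicators undefined for zero total cost"
        )
    profit = rs - ct
    denom = pig_price_kg * weight_kg
    if denom <= 0.0:
        raise UndefinedIndicatorError(
            "leveling point undefined for zero sale price or weight"
        )
    leveling = ct / denom
    rbc = rs / ct
    roi = profit / ct
    return profit, leveling, rbc, roi


def producer_income(profit: float, opportunity: float, beta: float) -> float:
    """Producer's total weekly income: profit + opportunity costs of
    own capital and land (a cost of the activity, but income to its
    owner) + remuneration of producer/family labor (beta). beta never
    enters the cost ledger."""
    return profit + opportunity + beta


@dataclass(frozen=True)
class BatchReport:
    """Economic indicator suite for one weekly batch.

    Ratio indicators are ``None`` when undefined (zero-cost or empty
    batch); the report writer renders those as "n/a".
    """

    operating_cost: float
    total_cost: float
    cost_per_head: float
    cost_per_arroba: float
    cost_per_kg: float
    revenue: float
    revenue_per_head: float
    revenue_per_kg: float
    profit: Optional[float] = None
    leveling_point: Optional[float] = None  # head
    benefit_cost_ratio: Optional[float] = None  # fraction
    roi: Optional[float] = None  # fraction
    producer_income: Optional[float] = None
    producer_income_per_kg: Optional[float] = None
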