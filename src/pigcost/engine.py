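"""End-to-end computation of one weekly batch for one farm."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .fixed import FixedCosts, compute_fixed_costs
from .herd import BatchFlow, compute_batch_flow
from .indicators import (
    BatchReport,
    producer_income,
    profitability,
    revenue,
    total_cost,
    unit_costs,
)
from .ledger import CostLedger, build_ledger
from .models import FarmConfig
from .opportunity import OpportunityCosts, compute_opportunity_costs
from .timebase import TIME_BASIS, TimeBasis
from .validation import errors as _errors, validate_config
from .variable import VariableCosts, compute_variable_costs


@dataclass(frozen=True)
class BatchResult:
    """Everything computed for one farm's weekly batch."""

    flow: BatchFlow
    variable: VariableCosts
    fixed: FixedCosts
    opportunity: OpportunityCosts
    ledger: CostLedger
    report: BatchReport


def compute_batch(
    cfg: FarmConfig, tb: TimeBasis = TIME_BASIS, *, validate: bool = True
) -> BatchResult:
    """Run the full model: herd flow, cost groups, ledger, indicators.

    With ``validate`` (the default) the configuration is checked first
    and any error-severity finding aborts the computation.
    """
    if validate:
        bad = _errors(validate_config(cfg))
        if bad:
            raise ConfigError(
                "invalid configuration: " + "; ".join(str(f) for f in bad)
            )

    flow = compute_batch_flow(cfg.herd, tb)
    var = compute_variable_costs(cfg, flow, tb)
    fx = compute_fixed_costs(cfg, tb)
    opp = compute_opportunity_costs(cfg, var.raising_subtotal, tb)
    ledger = build_ledger(var, fx, opp)

    cop, ct = total_cost(var.total, fx.total, opp.total)
    per_head, per_arroba, per_kg = unit_costs(
        ct, flow.finished_head, cfg.herd.finished_pig_weight_kg, tb
    )
    rs, r_head, r_kg = revenue(
        flow.batch_weight_kg, flow.cull_weight_kg, cfg.market,
        flow.finished_head,
    )

    if ct > 0 and cfg.market.pig_price_kg > 0 and cfg.herd.finished_pig_weight_kg > 0:
        profit, leveling, rbc, roi = profitability(
            rs, ct, cfg.market.pig_price_kg, cfg.herd.finished_pig_weight_kg
        )
        income = producer_income(profit, opp.total, cfg.market.family_labor_week)
        income_kg = (
            income / flow.batch_weight_kg if flow.batch_weight_kg > 0 else None
        )
    else:
        # degenerate farm (zero cost or zero market price): the ratio
        # indicators are undefined and reported as such
        profit = rs - ct
        leveling = rbc = roi = None
        income = producer_income(profit, opp.total, cfg.market.family_labor_week)
        income_kg = None

    report = BatchReport(
        operating_cost=cop,
        total_cost=ct,
        cost_per_head=per_head,
        cost_per_arroba=per_arroba,
        cost_per_kg=per_kg,
        revenue=rs,
        revenue_per_head=r_head,
        revenue_per_kg=r_kg,
        profit=profit,
        leveling_point=leveling,
        benefit_cost_ratio=rbc,
        roi=roi,
        producer_income=income,
        producer_income_per_kg=income_kg,
    )
    return BatchResult(
        flow=flow, variable=var, fixed=fx, opportunity=opp,
        ledger=ledger, report=report,
    )
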