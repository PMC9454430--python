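"""Variable costs of the weekly batch (ledger group A).

Variable costs move with the quantity produced: feed, health products,
reproduction inputs and consumables (together the *raising subtotal* —
the cash that goes directly into the animals), plus batch transport and
insurance, plus the prorated variable taxes and fees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .herd import BatchFlow
from .models import (
    ConsumerGood,
    DietLine,
    FarmConfig,
    HealthLine,
    ReproPlan,
    TransportInsurance,
    VariableTaxes,
)
from .timebase import TIME_BASIS, TimeBasis


@dataclass(frozen=True)
class CostLine:
    label: str
    amount: float


def _population(
    populations: dict[tuple[str, str], float], category: str, phase: str,
    register: str,
) -> float:
    try:
        return populations[(category, phase)]
    except KeyError:
        raise ConfigError(
            f"{register} line references unknown herd cell "
            f"({category!r}, {phase!r})"
        ) from None


def feed_costs(
    diets: list[DietLine], populations: dict[tuple[str, str], float]
) -> tuple[list[CostLine], float]:
    """Weekly feed cost per diet line and the feed subtotal.

    Per line: consumption/animal = days x kg/day; line cost = price x
    consumption/animal x head in the phase.
    """
    lines = []
    for d in diets:
        n = _population(populations, d.category, d.phase, "diet")
        per_animal = d.days_per_cycle * d.kg_per_day
        lines.append(
            CostLine(
                f"feed {d.category}/{d.phase}",
                d.price_per_kg * per_animal * n,
            )
        )
    return lines, sum(l.amount for l in lines)


def health_costs(
    health: list[HealthLine], populations: dict[tuple[str, str], float]
) -> tuple[list[CostLine], float]:
    """Weekly vaccine/medicine cost per line and the health subtotal."""
    lines = []
    for h in health:
        n = _population(populations, h.category, h.phase, "health")
        lines.append(
            CostLine(
                f"health {h.item} {h.category}/{h.phase}",
                h.dose_price * h.doses_per_animal * n,
            )
        )
    return lines, sum(l.amount for l in lines)


def repro_costs(
    plan: ReproPlan, weekly_group: float
) -> tuple[list[CostLine], float]:
    """Weekly reproduction cost; the consuming population is the weekly
    sow group, whatever the semen scenario (on-farm, purchased, mixed).
    """
    lines = [
        CostLine(
            f"repro {line.item} ({line.source})",
            line.unit_price * line.units_per_female * weekly_group,
        )
        for line in plan.lines
    ]
    return lines, sum(l.amount for l in lines)


def consumer_goods_costs(
    goods: list[ConsumerGood], tb: TimeBasis = TIME_BASIS
) -> tuple[list[CostLine], float]:
    """Monthly consumables prorated to the week (divide by omega)."""
    lines = [
        CostLine(
            f"consumable {g.item}",
            g.unit_price * g.monthly_quantity / tb.omega,
        )
        for g in goods
    ]
    return lines, sum(l.amount for l in lines)


def raising_subtotal(
    feed: float, health: float, repro: float, goods: float
) -> float:
    """Cash spent directly on the animals: feed + health + repro +
    consumables. Also the base of the working-capital remuneration."""
    return feed + health + repro + goods


def transport_insurance(
    p: TransportInsurance,
    finished_head: float,
    finished_weight_kg: float,
    pig_price_kg: float,
) -> tuple[float, float, float]:
    """Haulage and insurance of the weekly batch.

    Transport = price/km x distance. Insurance = rate x capital invested
    in the batch (head x weight x market price), applied once per batch.

    Returns (transport, insurance, subtotal).
    """
    transport = p.price_per_km * p.distance_km
    invested = finished_head * finished_weight_kg * pig_price_kg
    insurance = p.insurance_rate * invested
    return transport, insurance, transport + insurance


def variable_financial(
    taxes: VariableTaxes, tb: TimeBasis = TIME_BASIS
) -> float:
    """Annual variable taxes and fees prorated to the week."""
    return taxes.total_annual / tb.phi


def total_variable(
    raising: float, transport_insurance_subtotal: float, financial: float
) -> float:
    return raising + transport_insurance_subtotal + financial


@dataclass(frozen=True)
class VariableCosts:
    """Group A of the ledger with full line-item breakdown."""

    feed_lines: list[CostLine] = field(default_factory=list)
    feed_total: float = 0.0
    health_lines: list[CostLine] = field(default_factory=list)
    health_total: float = 0.0
    repro_lines: list[CostLine] = field(default_factory=list)
    repro_total: float = 0.0
    goods_lines: list[CostLine] = field(default_factory=list)
    goods_total: float = 0.0
    raising_subtotal: float = 0.0
    transport: float = 0.0
    insurance: float = 0.0
    transport_insurance_subtotal: float = 0.0
    financial: float = 0.0
    total: float = 0.0


def compute_variable_costs(
    cfg: FarmConfig, flow: BatchFlow, tb: TimeBasis = TIME_BASIS
) -> VariableCosts:
    """Evaluate every group-A register against the weekly flow."""
    feed_lines, feed_total = feed_costs(cfg.diets, flow.populations)
    health_lines, health_total = health_costs(cfg.health, flow.populations)
    repro_lines, repro_total = repro_costs(cfg.repro, flow.weekly_group)
    goods_lines, goods_total = consumer_goods_costs(cfg.consumer_goods, tb)
    raising = raising_subtotal(feed_total, health_total, repro_total, goods_total)
    transport, insurance, taseg = transport_insurance(
        cfg.transport,
        flow.finished_head,
        cfg.herd.finished_pig_weight_kg,
        cfg.market.pig_price_kg,
    )
    financial = variable_financial(cfg.variable_taxes, tb)
    return VariableCosts(
        feed_lines=feed_lines,
        feed_total=feed_total,
        health_lines=health_lines,
        health_total=health_total,
        repro_lines=repro_lines,
        repro_total=repro_total,
        goods_lines=goods_lines,
        goods_total=goods_total,
        raising_subtotal=raising,
        transport=transport,
        insurance=insurance,
        transport_insurance_subtotal=taseg,
        financial=financial,
        total=total_variable(raising, taseg, financial),
    )
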