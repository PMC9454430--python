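"""Opportunity costs of the producer's own capital and land (group D).

The producer's immobilized capital, the working capital that funds the
raising of the animals, and the land under the activity all have an
alternative use; their foregone return is a cost of the enterprise (and,
symmetrically, income to the producer). Annual rates are simple
prorations to the week — no compounding, matching the weekly turning
period of the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import AssetLine, FarmConfig
from .timebase import TIME_BASIS, TimeBasis


def fixed_capital_remuneration(
    assets: list[AssetLine], annual_rate: float, tb: TimeBasis = TIME_BASIS
) -> float:
    """Weekly return foregone on the value of all capital assets."""
    total_value = sum(a.value for a in assets)
    return annual_rate * total_value / tb.phi


def working_capital_remuneration(
    raising_subtotal: float, annual_rate: float, tb: TimeBasis = TIME_BASIS
) -> float:
    """Weekly return foregone on the cash funding the raising of the
    animals (the feed+health+repro+consumables subtotal). The annual
    rate is prorated to one week of that expenditure."""
    return annual_rate * raising_subtotal / tb.phi


def land_remuneration(
    area_ha: float, lease_price_ha_year: float, tb: TimeBasis = TIME_BASIS
) -> float:
    """Weekly lease value foregone on the land used by the activity."""
    return area_ha * lease_price_ha_year / tb.phi


def total_opportunity(
    fixed_capital: float, working_capital: float, land: float
) -> float:
    return fixed_capital + working_capital + land


@dataclass(frozen=True)
class OpportunityCosts:
    """Group D of the ledger."""

    fixed_capital: float = 0.0
    working_capital: float = 0.0
    land: float = 0.0
    total: float = 0.0


def compute_opportunity_costs(
    cfg: FarmConfig, raising_subtotal: float, tb: TimeBasis = TIME_BASIS
) -> OpportunityCosts:
    opp = cfg.opportunity
    rci = fixed_capital_remuneration(cfg.assets, opp.fixed_capital_rate, tb)
    rcg = working_capital_remuneration(
        raising_subtotal, opp.working_capital_rate, tb
    )
    rct = land_remuneration(opp.land_area_ha, opp.lease_price_ha_year, tb)
    return OpportunityCosts(
        fixed_capital=rci,
        working_capital=rcg,
        land=rct,
        total=total_opportunity(rci, rcg, rct),
    )
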