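"""Fixed operating costs of the weekly batch (ledger group B).

Fixed operating costs do not move with one more pig produced: labor,
electricity, telephone/internet, fuel, straight-line depreciation of
capital assets, maintenance, and fixed annual taxes and fees.

Monthly-basis items (labor, utilities, fuel) divide by omega; annual-
basis items (depreciation, maintenance, fixed taxes) divide by phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .models import AssetLine, FarmConfig, FixedTaxes, FuelLine, LaborLine, UtilityParams
from .timebase import TIME_BASIS, TimeBasis
from .variable import CostLine


def labor_costs(
    lines: list[LaborLine], tb: TimeBasis = TIME_BASIS
) -> tuple[list[CostLine], float]:
    """Weekly labor cost per activity: (monthly salary / omega) x headcount."""
    out = [
        CostLine(
            f"labor {l.activity}",
            l.monthly_salary / tb.omega * l.employees,
        )
        for l in lines
    ]
    return out, sum(l.amount for l in out)


def utility_costs(
    u: UtilityParams, tb: TimeBasis = TIME_BASIS
) -> tuple[float, float]:
    """Weekly electricity and phone/internet costs.

    The swine-activity share is applied before the monthly-to-weekly
    conversion, imputing only the portion the pig enterprise uses.
    Returns (electricity, phone_internet).
    """
    electricity = u.share * u.electricity_price_kwh * u.electricity_kwh_month / tb.omega
    phone_internet = u.share * (u.phone_month + u.internet_month) / tb.omega
    return electricity, phone_internet


def fuel_costs(
    lines: list[FuelLine], tb: TimeBasis = TIME_BASIS
) -> tuple[list[CostLine], float]:
    """Weekly fuel cost; each line carries its own apportionment share."""
    out = [
        CostLine(
            f"fuel {l.fuel}",
            l.share * l.price_per_litre * l.litres_per_month / tb.omega,
        )
        for l in lines
    ]
    return out, sum(l.amount for l in out)


def _annual_depreciation(asset: AssetLine) -> float:
    if asset.useful_life_years <= 0:
        raise ConfigError(
            f"asset {asset.asset!r}: useful life must be positive"
        )
    residual = asset.value * asset.residual_rate
    return (asset.value - residual) / asset.useful_life_years


def depreciation_costs(
    assets: list[AssetLine], tb: TimeBasis = TIME_BASIS
) -> tuple[list[CostLine], float]:
    """Straight-line depreciation, annual per asset, summed weekly.

    Annual charge = (value - residual) / useful life; the weekly total
    is the sum of annual charges divided by phi.
    """
    out = [
        CostLine(
            f"depreciation {a.asset} ({a.asset_class})",
            _annual_depreciation(a) / tb.phi,
        )
        for a in assets
    ]
    return out, sum(l.amount for l in out)


def maintenance_costs(
    assets: list[AssetLine], tb: TimeBasis = TIME_BASIS
) -> tuple[list[CostLine], float]:
    """Annual maintenance = manager's rate x asset value; summed weekly."""
    out = [
        CostLine(
            f"maintenance {a.asset} ({a.asset_class})",
            a.value * a.maintenance_rate / tb.phi,
        )
        for a in assets
    ]
    return out, sum(l.amount for l in out)


def fixed_financial(taxes: FixedTaxes, tb: TimeBasis = TIME_BASIS) -> float:
    """Annual fixed taxes and fees prorated to the week."""
    return taxes.total_annual / tb.phi


def total_fixed(
    labor: float,
    electricity: float,
    phone_internet: float,
    fuel: float,
    depreciation: float,
    maintenance: float,
    financial: float,
) -> float:
    return (
        labor + electricity + phone_internet + fuel
        + depreciation + maintenance + financial
    )


@dataclass(frozen=True)
class FixedCosts:
    """Group B of the ledger with full line-item breakdown."""

    labor_lines: list[CostLine] = field(default_factory=list)
    labor_total: float = 0.0
    electricity: float = 0.0
    phone_internet: float = 0.0
    fuel_lines: list[CostLine] = field(default_factory=list)
    fuel_total: float = 0.0
    depreciation_lines: list[CostLine] = field(default_factory=list)
    depreciation_total: float = 0.0
    maintenance_lines: list[CostLine] = field(default_factory=list)
    maintenance_total: float = 0.0
    financial: float = 0.0
    total: float = 0.0


def compute_fixed_costs(
    cfg: FarmConfig, tb: TimeBasis = TIME_BASIS
) -> FixedCosts:
    """Evaluate every group-B register."""
    labor_lines, labor_total = labor_costs(cfg.labor, tb)
    electricity, phone_internet = utility_costs(cfg.utilities, tb)
    fuel_lines, fuel_total = fuel_costs(cfg.fuels, tb)
    dep_lines, dep_total = depreciation_costs(cfg.assets, tb)
    man_lines, man_total = maintenance_costs(cfg.assets, tb)
    financial = fixed_financial(cfg.fixed_taxes, tb)
    return FixedCosts(
        labor_lines=labor_lines,
        labor_total=labor_total,
        electricity=electricity,
        phone_internet=phone_internet,
        fuel_lines=fuel_lines,
        fuel_total=fuel_total,
        depreciation_lines=dep_lines,
        depreciation_total=dep_total,
        maintenance_lines=man_lines,
        maintenance_total=man_total,
        financial=financial,
        total=total_fixed(
            labor_total, electricity, phone_internet, fuel_total,
            dep_total, man_total, financial,
        ),
    )
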