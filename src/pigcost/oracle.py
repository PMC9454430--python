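"""Independent flat-enumeration oracle for the total weekly cost.

This module re-derives the complete cost ledger from a
:class:`~pigcost.models.FarmConfig` in a single first-principles pass,
without reusing any of the engine's cost modules. It exists so that the
test suite can compare two independently written routes to the same
number; it is not part of the computation path users run.

Every line item of groups A, B and D is appended to one flat list and
summed; the weekly conversion constants are restated locally rather
than imported, to keep the two implementations decoupled.
"""

from __future__ import annotations

from .models import FarmConfig

_WEEKS_PER_MONTH = 4.345
_WEEKS_PER_YEAR = 365.0 / 7.0


def oracle_cost_items(cfg: FarmConfig) -> list[tuple[str, float]]:
    """Enumerate every weekly cost line item (groups A, B and D)."""
    items: list[tuple[str, float]] = []
    herd = cfg.herd

    # herd flow, restated
    gs = (
        herd.sows_in_production
        * herd.farrowings_per_sow_year
        * herd.farrowing_rate
        / _WEEKS_PER_YEAR
    )
    counts: dict[tuple[str, str], float] = {}
    cohort = gs * herd.born_alive_per_farrowing
    finished = cohort
    for ph in herd.phases:
        if ph.head_count is None:
            cohort = cohort * (1.0 - ph.mortality)
            counts[(ph.category, ph.phase)] = cohort
            finished = cohort
        else:
            counts[(ph.category, ph.phase)] = ph.head_count

    raising = 0.0
    for d in cfg.diets:
        amount = (
            d.price_per_kg
            * d.days_per_cycle
            * d.kg_per_day
            * counts[(d.category, d.phase)]
        )
        items.append((f"A/feed/{d.category}/{d.phase}", amount))
        raising += amount
    for h in cfg.health:
        amount = h.dose_price * h.doses_per_animal * counts[(h.category, h.phase)]
        items.append((f"A/health/{h.category}/{h.phase}/{h.item}", amount))
        raising += amount
    for r in cfg.repro.lines:
        amount = r.unit_price * r.units_per_female * gs
        items.append((f"A/repro/{r.item}", amount))
        raising += amount
    for g in cfg.consumer_goods:
        amount = g.unit_price * g.monthly_quantity / _WEEKS_PER_MONTH
        items.append((f"A/goods/{g.item}", amount))
        raising += amount

    items.append(
        ("A/transport", cfg.transport.price_per_km * cfg.transport.distance_km)
    )
    items.append(
        (
            "A/insurance",
            cfg.transport.insurance_rate
            * finished
            * herd.finished_pig_weight_kg
            * cfg.market.pig_price_kg,
        )
    )
    vt = cfg.variable_taxes
    items.append(
        (
            "A/variable-taxes",
            (vt.icms_annual + vt.gta_annual + vt.funrural_annual + vt.other_annual)
            / _WEEKS_PER_YEAR,
        )
    )

    for l in cfg.labor:
        items.append(
            (
                f"B/labor/{l.activity}",
                l.monthly_salary / _WEEKS_PER_MONTH * l.employees,
            )
        )
    u = cfg.utilities
    items.append(
        (
            "B/electricity",
            u.share * u.electricity_price_kwh * u.electricity_kwh_month
            / _WEEKS_PER_MONTH,
        )
    )
    items.append(
        (
            "B/phone-internet",
            u.share * (u.phone_month + u.internet_month) / _WEEKS_PER_MONTH,
        )
    )
    for fu in cfg.fuels:
        items.append(
            (
                f"B/fuel/{fu.fuel}",
                fu.share * fu.price_per_litre * fu.litres_per_month
                / _WEEKS_PER_MONTH,
            )
        )
    for a in cfg.assets:
        value = a.unit_price * a.quantity
        annual_dep = (value - value * a.residual_rate) / a.useful_life_years
        items.append((f"B/depreciation/{a.asset}", annual_dep / _WEEKS_PER_YEAR))
        items.append(
            (
                f"B/maintenance/{a.asset}",
                value * a.maintenance_rate / _WEEKS_PER_YEAR,
            )
        )
    ft = cfg.fixed_taxes
    items.append(
        (
            "B/fixed-taxes",
            (ft.itr_annual + ft.fees_annual + ft.other_annual) / _WEEKS_PER_YEAR,
        )
    )

    opp = cfg.opportunity
    asset_value = sum(a.unit_price * a.quantity for a in cfg.assets)
    items.append(
        (
            "D/fixed-capital",
            opp.fixed_capital_rate * asset_value / _WEEKS_PER_YEAR,
        )
    )
    items.append(
        (
            "D/working-capital",
            opp.working_capital_rate * raising / _WEEKS_PER_YEAR,
        )
    )
    items.append(
        (
            "D/land",
            opp.land_area_ha * opp.lease_price_ha_year / _WEEKS_PER_YEAR,
        )
    )
    return items


def oracle_total_cost(cfg: FarmConfig) -> float:
    """Total weekly cost as the plain sum of the flat enumeration."""
    return sum(amount for _, amount in oracle_cost_items(cfg))
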