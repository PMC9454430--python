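"""Seeded synthetic-farm generator and price-perturbation helpers.

:func:`generate_farm` produces a complete, valid configuration of a
plausible Brazilian full-cycle farm at three size classes (sow-herd
ranges 50-200, 200-1000, 1000-5000 head). The parameter bounds in
``BOUNDS`` are arbitrary test scaffolding — plausible magnitudes for a
commercial operation, not data from any real farm. All draws are
uniform within their bounds, and every register uses its own named
random stream so that adding a register never shifts the draws of the
others for a fixed seed; identical (seed, size class) inputs give
identical configurations.

:func:`scale_prices` and :func:`bump_price` perturb the monetary inputs
of an existing configuration (leaving herd structure and rates fixed),
which is how the cost homogeneity and monotonicity properties are
exercised and how users can script simple price sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .models import (
    AssetLine,
    ConsumerGood,
    CullParams,
    DietLine,
    FarmConfig,
    FixedTaxes,
    FuelLine,
    HealthLine,
    HerdParams,
    LaborLine,
    MarketParams,
    OpportunityParams,
    PhaseDef,
    ReproLine,
    ReproPlan,
    TransportInsurance,
    UtilityParams,
    VariableTaxes,
)

SizeClass = Literal["small", "medium", "large"]

#: Sow-herd size ranges per class, head.
SIZE_CLASSES: dict[str, tuple[int, int]] = {
    "small": (50, 200),
    "medium": (200, 1000),
    "large": (1000, 5000),
}

#: Uniform-draw bounds for the generator (plausible magnitudes only).
BOUNDS: dict[str, tuple[float, float]] = {
    "farrowings_per_sow_year": (2.2, 2.5),
    "farrowing_rate": (0.85, 0.93),
    "born_alive": (11.0, 15.0),
    "finished_weight_kg": (105.0, 130.0),
    "mort_farrowing": (0.04, 0.10),
    "mort_nursery": (0.01, 0.04),
    "mort_growing": (0.005, 0.02),
    "mort_finishing": (0.005, 0.02),
    "sow_cull_rate": (0.35, 0.45),
    "sow_cull_weight": (200.0, 250.0),
    "boar_cull_rate": (0.30, 0.50),
    "boar_cull_weight": (250.0, 300.0),
    "diet_price": (1.2, 2.6),
    "dose_price": (0.5, 5.0),
    "doses": (1.0, 3.0),
    "semen_dose_price": (15.0, 30.0),
    "ai_material_price": (1.0, 4.0),
    "good_price": (5.0, 100.0),
    "good_qty": (1.0, 20.0),
    "km_price": (5.0, 12.0),
    "distance_km": (30.0, 250.0),
    "insurance_rate": (0.001, 0.004),
    "var_tax_per_sow": (5.0, 40.0),
    "salary": (2500.0, 4500.0),
    "kwh_price": (0.6, 1.0),
    "kwh_per_sow": (8.0, 15.0),
    "phone": (50.0, 150.0),
    "internet": (80.0, 200.0),
    "share": (0.8, 1.0),
    "diesel_price": (5.0, 7.0),
    "diesel_litres_per_sow": (0.5, 2.0),
    "housing_per_sow": (2000.0, 4000.0),
    "machinery_per_sow": (150.0, 400.0),
    "sow_price": (2000.0, 3500.0),
    "residual_building": (0.05, 0.20),
    "life_building": (20.0, 30.0),
    "life_machinery": (8.0, 15.0),
    "residual_sow": (0.30, 0.50),
    "life_sow": (2.5, 4.0),
    "maintenance_rate": (0.01, 0.03),
    "fixed_tax": (500.0, 5000.0),
    "capital_rate": (0.04, 0.14),
    "ha_per_100_sows": (1.0, 3.0),
    "lease_price": (500.0, 2000.0),
    "pig_price_kg": (5.0, 8.0),
    "cull_price_kg": (3.0, 5.0),
    "family_labor": (500.0, 2000.0),
}

# Stable stream ids; append-only so existing draws never shift.
_STREAMS = {
    "herd": 0,
    "diets": 1,
    "health": 2,
    "repro": 3,
    "consumer_goods": 4,
    "transport": 5,
    "variable_taxes": 6,
    "labor": 7,
    "utilities": 8,
    "fuels": 9,
    "assets": 10,
    "fixed_taxes": 11,
    "opportunity": 12,
    "market": 13,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Seeded recipe for one synthetic farm."""

    seed: int
    size_class: SizeClass = "medium"


def _rng(spec: ScenarioSpec, stream: str) -> np.random.Generator:
    size_index = list(SIZE_CLASSES).index(spec.size_class)
    return np.random.default_rng([spec.seed, size_index, _STREAMS[stream]])


def _u(rng: np.random.Generator, key: str) -> float:
    lo, hi = BOUNDS[key]
    return float(rng.uniform(lo, hi))


def generate_farm(spec: ScenarioSpec) -> FarmConfig:
    """Generate one complete, valid farm configuration."""
    if spec.size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {spec.size_class!r}")

    rng = _rng(spec, "herd")
    lo, hi = SIZE_CLASSES[spec.size_class]
    n_sows = float(rng.integers(lo, hi + 1))
    boars = max(1.0, round(n_sows * 0.02))
    gilts = round(n_sows * 0.10)

    phases = [
        PhaseDef(category="piglet", phase="farrowing",
                 mortality=_u(rng, "mort_farrowing")),
        PhaseDef(category="piglet", phase="nursery",
                 mortality=_u(rng, "mort_nursery")),
        PhaseDef(category="grower", phase="growing",
                 mortality=_u(rng, "mort_growing")),
        PhaseDef(category="finisher", phase="finishing",
                 mortality=_u(rng, "mort_finishing")),
        PhaseDef(category="dam", phase="gestation",
                 head_count=round(n_sows * 0.80)),
        PhaseDef(category="dam", phase="lactation",
                 head_count=round(n_sows * 0.20)),
        PhaseDef(category="gilt", phase="adaptation", head_count=gilts),
        PhaseDef(category="boar", phase="service", head_count=boars),
    ]
    herd = HerdParams(
        sows_in_production=n_sows,
        farrowings_per_sow_year=_u(rng, "farrowings_per_sow_year"),
        farrowing_rate=_u(rng, "farrowing_rate"),
        born_alive_per_farrowing=_u(rng, "born_alive"),
        finished_pig_weight_kg=_u(rng, "finished_weight_kg"),
        phases=phases,
        culls=[
            CullParams(sex="female", head_on_farm=n_sows,
                       annual_cull_rate=_u(rng, "sow_cull_rate"),
                       cull_weight_kg=_u(rng, "sow_cull_weight")),
            CullParams(sex="male", head_on_farm=boars,
                       annual_cull_rate=_u(rng, "boar_cull_rate"),
                       cull_weight_kg=_u(rng, "boar_cull_weight")),
        ],
    )

    rng = _rng(spec, "diets")
    # kg/day roughly tracks Brazilian feeding programs. Grow-out rows
    # charge the whole phase's feed (supply period = phase length in
    # days) to the weekly cohort; breeding rows with standing head
    # counts are fed on a 7-day weekly cycle.
    feeding = [
        ("piglet", "farrowing", 21.0, 0.05, 0.2),
        ("piglet", "nursery", 42.0, 0.4, 1.0),
        ("grower", "growing", 40.0, 1.5, 2.5),
        ("finisher", "finishing", 45.0, 2.5, 3.3),
        ("dam", "gestation", 7.0, 2.2, 2.8),
        ("dam", "lactation", 7.0, 5.0, 7.0),
        ("gilt", "adaptation", 7.0, 2.0, 3.0),
        ("boar", "service", 7.0, 2.2, 3.0),
    ]
    diets = [
        DietLine(category=c, phase=p, price_per_kg=_u(rng, "diet_price"),
                 days_per_cycle=days,
                 kg_per_day=float(rng.uniform(qlo, qhi)))
        for c, p, days, qlo, qhi in feeding
    ]

    rng = _rng(spec, "health")
    health = [
        HealthLine(category=c, phase=p, item=item,
                   dose_price=_u(rng, "dose_price"),
                   doses_per_animal=float(rng.integers(1, 4)))
        for c, p, item in (
            ("piglet", "farrowing", "iron+vaccine"),
            ("piglet", "nursery", "vaccine"),
            ("finisher", "finishing", "medication"),
            ("dam", "gestation", "vaccine"),
        )
    ]

    rng = _rng(spec, "repro")
    scenario = ("on_farm", "purchased", "mixed")[int(rng.integers(0, 3))]
    lines = [
        ReproLine(item="AI materials (pipettes, tubes)", source="purchased",
                  unit_price=_u(rng, "ai_material_price"),
                  units_per_female=3.0),
    ]
    if scenario in ("purchased", "mixed"):
        lines.append(
            ReproLine(item="commercial semen dose", source="purchased",
                      unit_price=_u(rng, "semen_dose_price"),
                      units_per_female=3.0)
        )
    if scenario in ("on_farm", "mixed"):
        lines.append(
            ReproLine(item="collection and processing supplies",
                      source="on_farm",
                      unit_price=_u(rng, "semen_dose_price") * 0.4,
                      units_per_female=3.0)
        )
    repro = ReproPlan(scenario=scenario, lines=lines)

    rng = _rng(spec, "consumer_goods")
    goods = [
        ConsumerGood(item=item, unit_price=_u(rng, "good_price"),
                     monthly_quantity=_u(rng, "good_qty"))
        for item in ("gloves", "needles and syringes", "marker sticks")
    ]

    rng = _rng(spec, "transport")
    transport = TransportInsurance(
        price_per_km=_u(rng, "km_price"),
        distance_km=_u(rng, "distance_km"),
        insurance_rate=_u(rng, "insurance_rate"),
    )

    rng = _rng(spec, "variable_taxes")
    variable_taxes = VariableTaxes(
        icms_annual=n_sows * _u(rng, "var_tax_per_sow"),
        gta_annual=n_sows * _u(rng, "var_tax_per_sow") * 0.2,
        funrural_annual=n_sows * _u(rng, "var_tax_per_sow") * 0.5,
        other_annual=n_sows * _u(rng, "var_tax_per_sow") * 0.1,
    )

    rng = _rng(spec, "labor")
    labor = [
        LaborLine(activity="barn staff", monthly_salary=_u(rng, "salary"),
                  employees=max(1.0, round(n_sows / 120.0))),
        LaborLine(activity="manager",
                  monthly_salary=_u(rng, "salary") * 1.5, employees=1.0),
    ]

    rng = _rng(spec, "utilities")
    utilities = UtilityParams(
        electricity_price_kwh=_u(rng, "kwh_price"),
        electricity_kwh_month=n_sows * _u(rng, "kwh_per_sow"),
        phone_month=_u(rng, "phone"),
        internet_month=_u(rng, "internet"),
        share=_u(rng, "share"),
    )

    rng = _rng(spec, "fuels")
    fuels = [
        FuelLine(fuel="diesel", price_per_litre=_u(rng, "diesel_price"),
                 litres_per_month=n_sows * _u(rng, "diesel_litres_per_sow"),
                 share=_u(rng, "share")),
        FuelLine(fuel="gasoline",
                 price_per_litre=_u(rng, "diesel_price") * 1.1,
                 litres_per_month=n_sows * _u(rng, "diesel_litres_per_sow") * 0.3),
    ]

    rng = _rng(spec, "assets")
    assets = [
        AssetLine(asset="barns and facilities", asset_class="housing",
                  unit_price=n_sows * _u(rng, "housing_per_sow"),
                  quantity=1.0,
                  residual_rate=_u(rng, "residual_building"),
                  useful_life_years=_u(rng, "life_building"),
                  maintenance_rate=_u(rng, "maintenance_rate")),
        AssetLine(asset="machinery and implements", asset_class="machinery",
                  unit_price=n_sows * _u(rng, "machinery_per_sow"),
                  quantity=1.0,
                  residual_rate=_u(rng, "residual_building"),
                  useful_life_years=_u(rng, "life_machinery"),
                  maintenance_rate=_u(rng, "maintenance_rate")),
        AssetLine(asset="breeding herd", asset_class="biological",
                  unit_price=_u(rng, "sow_price"),
                  quantity=n_sows + boars,
                  residual_rate=_u(rng, "residual_sow"),
                  useful_life_years=_u(rng, "life_sow"),
                  maintenance_rate=0.0),
    ]

    rng = _rng(spec, "fixed_taxes")
    fixed_taxes = FixedTaxes(
        itr_annual=_u(rng, "fixed_tax"),
        fees_annual=_u(rng, "fixed_tax") * 0.5,
        other_annual=_u(rng, "fixed_tax") * 0.2,
    )

    rng = _rng(spec, "opportunity")
    opportunity = OpportunityParams(
        fixed_capital_rate=_u(rng, "capital_rate"),
        working_capital_rate=_u(rng, "capital_rate"),
        land_area_ha=n_sows / 100.0 * _u(rng, "ha_per_100_sows"),
        lease_price_ha_year=_u(rng, "lease_price"),
    )

    rng = _rng(spec, "market")
    market = MarketParams(
        pig_price_kg=_u(rng, "pig_price_kg"),
        cull_price_kg=_u(rng, "cull_price_kg"),
        family_labor_week=_u(rng, "family_labor"),
    )

    return FarmConfig(
        name=f"synthetic-{spec.size_class}-{spec.seed}",
        herd=herd,
        diets=diets,
        health=health,
        repro=repro,
        consumer_goods=goods,
        transport=transport,
        variable_taxes=variable_taxes,
        labor=labor,
        utilities=utilities,
        fuels=fuels,
        assets=assets,
        fixed_taxes=fixed_taxes,
        opportunity=opportunity,
        market=market,
    )


# ---------------------------------------------------------------------------
# Price perturbation
# ---------------------------------------------------------------------------

#: Dotted paths of every monetary input that enters the cost ledger.
#: Rates, head counts and physical quantities are deliberately absent:
#: these helpers move prices only.
def price_paths(cfg: FarmConfig) -> list[tuple]:
    """(container, attribute) pairs for every price-like field."""
    paths: list[tuple] = []
    for d in cfg.diets:
        paths.append((d, "price_per_kg"))
    for h in cfg.health:
        paths.append((h, "dose_price"))
    for r in cfg.repro.lines:
        paths.append((r, "unit_price"))
    for g in cfg.consumer_goods:
        paths.append((g, "unit_price"))
    paths.append((cfg.transport, "price_per_km"))
    for f_ in ("icms_annual", "gta_annual", "funrural_annual", "other_annual"):
        paths.append((cfg.variable_taxes, f_))
    for l in cfg.labor:
        paths.append((l, "monthly_salary"))
    for f_ in ("electricity_price_kwh", "phone_month", "internet_month"):
        paths.append((cfg.utilities, f_))
    for fu in cfg.fuels:
        paths.append((fu, "price_per_litre"))
    for a in cfg.assets:
        paths.append((a, "unit_price"))
    for f_ in ("itr_annual", "fees_annual", "other_annual"):
        paths.append((cfg.fixed_taxes, f_))
    paths.append((cfg.opportunity, "lease_price_ha_year"))
    paths.append((cfg.market, "pig_price_kg"))
    paths.append((cfg.market, "cull_price_kg"))
    return paths


def scale_prices(cfg: FarmConfig, k: float) -> FarmConfig:
    """Return a copy with every monetary input multiplied by ``k``.

    With the herd fixed, every cost group — and the total cost — is
    homogeneous of degree one in prices, so scaling prices by ``k``
    scales the whole ledger by ``k``.
    """
    out = cfg.model_copy(deep=True)
    for obj, attr in price_paths(out):
        object.__setattr__(obj, attr, getattr(obj, attr) * k)
    return out


def bump_price(
    cfg: FarmConfig, rng: np.random.Generator, factor_range=(1.01, 2.0)
) -> tuple[FarmConfig, str]:
    """Return a copy with one randomly chosen price multiplied by a
    factor > 1, plus a label of what moved. Raising any single price
    can never decrease the total cost."""
    out = cfg.model_copy(deep=True)
    paths = price_paths(out)
    obj, attr = paths[int(rng.integers(0, len(paths)))]
    factor = float(rng.uniform(*factor_range))
    object.__setattr__(obj, attr, getattr(obj, attr) * factor)
    return out, f"{type(obj).__name__}.{attr} x{factor:.3f}"
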