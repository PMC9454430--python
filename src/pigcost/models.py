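"""Domain types describing one full-cycle swine farm.

A :class:`FarmConfig` is the complete validated description of a farm:
the breeding herd and its weekly production flow, the input registers
(diets, health products, reproduction inputs, consumer goods, labor,
fuels, capital assets), the tax and rate parameters, and the market
prices needed to value the weekly batch.

Structural constraints that make a configuration unreadable — negative
prices, negative quantities — are enforced here at parse time, with the
offending field named in the error. Range constraints on rates
(mortality, culling, apportionment shares) are checked separately by
:func:`pigcost.validation.validate_config`, which returns findings
rather than raising, so that a partially wrong configuration can be
inspected as a whole.

All monetary values are in one declared currency unit (``currency`` is a
label only; the arithmetic is currency-agnostic). Rates are fractions:
an annual culling rate of 40% is entered as ``0.40``.
"""

from __future__ import annotations

from typing import Annotated, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

# Monetary values and physical quantities must be non-negative to parse.
NonNeg = Annotated[float, Field(ge=0)]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


# ---------------------------------------------------------------------------
# Herd
# ---------------------------------------------------------------------------


class PhaseDef(_Model):
    """One (animal category, production phase) cell of the herd.

    Two kinds of rows coexist:

    * **Grow-out rows** (``head_count`` omitted): members of the ordered
      survival chain farrowing room -> nursery -> growing -> finishing.
      Their weekly head count is derived from the weekly sow group and
      the phase mortalities, in the order the rows are listed.
    * **Breeding rows** (``head_count`` given): gilts, dams, boars,
      ruffians. Their head count is part of the farm's standing
      structure and is entered directly; it is used for feed and health
      costing but does not enter the market-pig survival chain.
    """

    category: str
    phase: str
    mortality: float = 0.0  # fraction lost in the phase, grow-out rows
    head_count: Optional[NonNeg] = None  # standing count, breeding rows

    @property
    def is_growout(self) -> bool:
        return self.head_count is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.phase)


class CullParams(_Model):
    """Annual culling of the breeding herd, one row per sex.

    Culls are sold by live weight alongside the weekly batch; the annual
    rate is prorated to a weekly kilogram figure.
    """

    sex: Literal["female", "male"]
    head_on_farm: NonNeg  # breeding animals of that sex on the farm
    annual_cull_rate: float  # fraction of the herd removed per year
    cull_weight_kg: NonNeg  # live weight at sale, kg/head


class HerdParams(_Model):
    """Breeding-herd demography and grow-out phase structure."""

    sows_in_production: NonNeg  # N, head
    farrowings_per_sow_year: NonNeg  # litters per sow per year
    farrowing_rate: float  # fraction of services that farrow
    born_alive_per_farrowing: NonNeg  # piglets born alive per litter
    finished_pig_weight_kg: NonNeg  # average live weight at sale, kg
    phases: list[PhaseDef] = Field(default_factory=list)
    culls: list[CullParams] = Field(default_factory=list)

    def growout_phases(self) -> list[PhaseDef]:
        return [p for p in self.phases if p.is_growout]

    def phase_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.phases}


# ---------------------------------------------------------------------------
# Variable-cost registers
# ---------------------------------------------------------------------------


class DietLine(_Model):
    """One diet fed to one (category, phase).

    Consumption per animal is ``days_per_cycle * kg_per_day``; the line
    cost is that consumption times the phase head count times the diet
    price.
    """

    category: str
    phase: str
    price_per_kg: NonNeg
    days_per_cycle: NonNeg  # supply period of the diet, days
    kg_per_day: NonNeg  # amount fed per animal per day


class HealthLine(_Model):
    """Vaccine or medicine applied to one (category, phase)."""

    category: str
    phase: str
    item: str = "dose"
    dose_price: NonNeg
    doses_per_animal: NonNeg


class ReproLine(_Model):
    """One reproduction input consumed per inseminated female.

    Covers both on-farm semen production (collection and processing
    supplies, lab consumables) and purchased doses from an AI center;
    either way the consuming population is the weekly sow group.
    """

    item: str
    source: Literal["on_farm", "purchased"] = "purchased"
    unit_price: NonNeg
    units_per_female: NonNeg


class ReproPlan(_Model):
    """Reproduction scenario: on-farm semen, purchased semen, or both."""

    scenario: Literal["on_farm", "purchased", "mixed"] = "purchased"
    lines: list[ReproLine] = Field(default_factory=list)


class ConsumerGood(_Model):
    """Consumable bought monthly (gloves, needles, syringes, ...)."""

    item: str
    unit_price: NonNeg
    monthly_quantity: NonNeg


class TransportInsurance(_Model):
    """Haulage of the batch to the slaughterhouse plus batch insurance.

    Insurance is a per-batch rate applied once to the capital invested
    in the batch (finished head x weight x market price).
    """

    price_per_km: NonNeg = 0.0
    distance_km: NonNeg = 0.0
    insurance_rate: NonNeg = 0.0  # fraction of batch invested capital


class VariableTaxes(_Model):
    """Variable taxes and fees, entered as annual currency amounts.

    ICMS (goods-circulation tax), GTA (animal transit guide fees) and
    Funrural (rural worker fund levy) are Brazilian examples; the model
    takes the amounts as user inputs and prorates them to the week.
    """

    icms_annual: NonNeg = 0.0
    gta_annual: NonNeg = 0.0
    funrural_annual: NonNeg = 0.0
    other_annual: NonNeg = 0.0

    @property
    def total_annual(self) -> float:
        return (
            self.icms_annual
            + self.gta_annual
            + self.funrural_annual
            + self.other_annual
        )


# ---------------------------------------------------------------------------
# Fixed-operating-cost registers
# ---------------------------------------------------------------------------


class LaborLine(_Model):
    """Employees of one activity; salary is monthly, charges included.

    Labor is a fixed operating cost in this model: headcount does not
    move with one more pig produced.
    """

    activity: str
    monthly_salary: NonNeg  # per employee, with charges
    employees: NonNeg


class UtilityParams(_Model):
    """Electricity, telephone and internet, on a monthly basis.

    ``share`` is the fraction of the bills attributable to the swine
    activity when the farm runs other enterprises; it applies to both
    electricity and phone/internet before weekly conversion.
    """

    electricity_price_kwh: NonNeg = 0.0
    electricity_kwh_month: NonNeg = 0.0
    phone_month: NonNeg = 0.0
    internet_month: NonNeg = 0.0
    share: float = 1.0


class FuelLine(_Model):
    """Monthly consumption of one fuel (diesel, gasoline, alcohol)."""

    fuel: str
    price_per_litre: NonNeg
    litres_per_month: NonNeg
    share: float = 1.0  # swine-activity apportionment


class AssetLine(_Model):
    """One capital asset: buildings, machinery or biological assets.

    Straight-line depreciation with user-entered useful life and
    residual fraction; the model is managerial, so breeding animals may
    be depreciated the same way (residual = cull value fraction).
    Maintenance is an annual fraction of the asset value.
    """

    asset: str
    asset_class: Literal["housing", "machinery", "biological"] = "housing"
    unit_price: NonNeg
    quantity: NonNeg = 1.0
    residual_rate: float = 0.0  # fraction of value kept at end of life
    useful_life_years: float = 1.0
    maintenance_rate: NonNeg = 0.0  # annual fraction of value

    @property
    def value(self) -> float:
        return self.unit_price * self.quantity


class FixedTaxes(_Model):
    """Fixed annual taxes and fees (rural land tax, memberships...)."""

    itr_annual: NonNeg = 0.0
    fees_annual: NonNeg = 0.0
    other_annual: NonNeg = 0.0

    @property
    def total_annual(self) -> float:
        return self.itr_annual + self.fees_annual + self.other_annual


# ---------------------------------------------------------------------------
# Opportunity costs and market
# ---------------------------------------------------------------------------


class OpportunityParams(_Model):
    """Remuneration of the producer's own capital and land.

    The annual rates are chosen by the manager (e.g. the Selic reference
    rate); the land opportunity cost uses the regional lease price.
    Rates above 1 (100%/yr) are flagged as suspicious by validation
    unless ``rates_above_one_ok`` is set.
    """

    fixed_capital_rate: NonNeg = 0.0  # fraction per year on asset value
    working_capital_rate: NonNeg = 0.0  # fraction per year on raising cost
    land_area_ha: NonNeg = 0.0
    lease_price_ha_year: NonNeg = 0.0
    rates_above_one_ok: bool = False


class MarketParams(_Model):
    """Sale prices and the producer's own labor remuneration."""

    pig_price_kg: NonNeg = 0.0  # market pig, per live kg
    cull_price_kg: NonNeg = 0.0  # cull animal, per live kg
    family_labor_week: NonNeg = 0.0  # producer/family remuneration, per week


# ---------------------------------------------------------------------------
# The farm
# ---------------------------------------------------------------------------


class FarmConfig(_Model):
    """Complete description of one full-cycle farm."""

    name: str = "farm"
    currency: str = "BRL"
    herd: HerdParams
    diets: list[DietLine] = Field(default_factory=list)
    health: list[HealthLine] = Field(default_factory=list)
    repro: ReproPlan = Field(default_factory=ReproPlan)
    consumer_goods: list[ConsumerGood] = Field(default_factory=list)
    transport: TransportInsurance = Field(default_factory=TransportInsurance)
    variable_taxes: VariableTaxes = Field(default_factory=VariableTaxes)
    labor: list[LaborLine] = Field(default_factory=list)
    utilities: UtilityParams = Field(default_factory=UtilityParams)
    fuels: list[FuelLine] = Field(default_factory=list)
    assets: list[AssetLine] = Field(default_factory=list)
    fixed_taxes: FixedTaxes = Field(default_factory=FixedTaxes)
    opportunity: OpportunityParams = Field(default_factory=OpportunityParams)
    market: MarketParams = Field(default_factory=MarketParams)
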