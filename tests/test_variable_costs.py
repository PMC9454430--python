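"""Group A: feed, health, reproduction, consumables, transport, taxes."""

import pytest

from pigcost.errors import ConfigError
from pigcost.models import (
    ConsumerGood,
    DietLine,
    HealthLine,
    ReproLine,
    ReproPlan,
    TransportInsurance,
    VariableTaxes,
)
from pigcost.variable import (
    consumer_goods_costs,
    feed_costs,
    health_costs,
    raising_subtotal,
    repro_costs,
    total_variable,
    transport_insurance,
    variable_financial,
)

POPS = {("pig", "grow"): 5.0, ("piglet", "farrowing"): 114.0}


class TestFeed:
    def test_worked_example(self):
        lines, total = feed_costs(
            [DietLine(category="pig", phase="grow", price_per_kg=1.50,
                      days_per_cycle=10.0, kg_per_day=2.0)],
            POPS,
        )
        assert total == pytest.approx(150.0)  # 1.5 x (10 x 2 x 5)

    def test_zero_quantity(self):
        _, total = feed_costs(
            [DietLine(category="pig", phase="grow", price_per_kg=1.5,
                      days_per_cycle=10.0, kg_per_day=0.0)],
            POPS,
        )
        assert total == 0.0

    def test_two_identical_lines_additive(self):
        line = DietLine(category="pig", phase="grow", price_per_kg=1.5,
                        days_per_cycle=10.0, kg_per_day=2.0)
        _, total = feed_costs([line, line], POPS)
        assert total == pytest.approx(300.0)

    def test_unknown_cell_rejected(self):
        with pytest.raises(ConfigError, match="unknown herd cell"):
            feed_costs(
                [DietLine(category="ghost", phase="grow", price_per_kg=1.0,
                          days_per_cycle=1.0, kg_per_day=1.0)],
                POPS,
            )


class TestHealth:
    def test_worked_example(self):
        _, total = health_costs(
            [HealthLine(category="piglet", phase="farrowing",
                        dose_price=2.50, doses_per_animal=2.0)],
            POPS,
        )
        assert total == pytest.approx(570.0)  # 2.5 x 2 x 114

    def test_identity_prices(self):
        _, total = health_costs(
            [HealthLine(category="pig", phase="grow", dose_price=1.0,
                        doses_per_animal=1.0)],
            POPS,
        )
        assert total == POPS[("pig", "grow")]


class TestRepro:
    def test_weekly_group_is_the_consumer(self):
        plan = ReproPlan(scenario="purchased", lines=[
            ReproLine(item="semen", unit_price=20.0, units_per_female=3.0),
        ])
        _, total = repro_costs(plan, weekly_group=10.0)
        assert total == pytest.approx(600.0)

    def test_empty_plan(self):
        assert repro_costs(ReproPlan(), 10.0)[1] == 0.0

    def test_mixed_scenario_sums_both_sources(self):
        plan = ReproPlan(scenario="mixed", lines=[
            ReproLine(item="on-farm supplies", source="on_farm",
                      unit_price=5.0, units_per_female=1.0),
            ReproLine(item="semen", source="purchased",
                      unit_price=20.0, units_per_female=1.0),
        ])
        _, total = repro_costs(plan, 10.0)
        assert total == pytest.approx(250.0)


class TestConsumerGoods:
    def test_monthly_to_weekly_ratio(self):
        _, total = consumer_goods_costs(
            [ConsumerGood(item="gloves", unit_price=10.0,
                          monthly_quantity=4.345)]
        )
        assert total == pytest.approx(10.0)

    def test_monthly_spend_divided_by_omega(self):
        _, total = consumer_goods_costs(
            [ConsumerGood(item="x", unit_price=1.0, monthly_quantity=869.0)]
        )
        assert total == pytest.approx(869.0 / 4.345)


class TestTransportInsurance:
    def test_worked_example(self):
        transport, insurance, subtotal = transport_insurance(
            TransportInsurance(price_per_km=8.50, distance_km=120.0,
                               insurance_rate=0.002),
            finished_head=100.0, finished_weight_kg=115.0, pig_price_kg=6.00,
        )
        assert transport == pytest.approx(1020.0)
        assert insurance == pytest.approx(138.0)  # 0.002 x 100 x 115 x 6
        assert subtotal == pytest.approx(1158.0)

    def test_no_insurance(self):
        _, _, subtotal = transport_insurance(
            TransportInsurance(price_per_km=8.5, distance_km=120.0),
            100.0, 115.0, 6.0,
        )
        assert subtotal == pytest.approx(1020.0)


class TestFinancialAndTotals:
    def test_annual_proration(self):
        taxes = VariableTaxes(icms_annual=100.0, gta_annual=100.0,
                              funrural_annual=100.0, other_annual=65.0)
        assert variable_financial(taxes) == pytest.approx(7.0)  # 365/yr

    def test_linearity(self):
        one = variable_financial(VariableTaxes(icms_annual=500.0))
        two = variable_financial(VariableTaxes(icms_annual=1000.0))
        assert two == pytest.approx(2.0 * one)

    def test_raising_subtotal_and_variable_total(self):
        assert raising_subtotal(150.0, 570.0, 600.0, 10.0) == 1330.0
        assert total_variable(1330.0, 1158.0, 7.0) == 2495.0
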