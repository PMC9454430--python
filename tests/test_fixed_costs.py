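"""Group B: labor, utilities, fuel, depreciation, maintenance, taxes."""

import pytest

from pigcost.errors import ConfigError
from pigcost.fixed import (
    depreciation_costs,
    fixed_financial,
    fuel_costs,
    labor_costs,
    maintenance_costs,
    total_fixed,
    utility_costs,
)
from pigcost.models import AssetLine, FixedTaxes, FuelLine, LaborLine, UtilityParams
from pigcost.timebase import TIME_BASIS


def asset(price=100000.0, qty=1.0, residual=0.10, life=10.0, maint=0.0):
    return AssetLine(asset="barn", unit_price=price, quantity=qty,
                     residual_rate=residual, useful_life_years=life,
                     maintenance_rate=maint)


class TestLabor:
    def test_monthly_salary_to_weekly(self):
        _, total = labor_costs(
            [LaborLine(activity="barn", monthly_salary=4345.0, employees=2.0)]
        )
        assert total == pytest.approx(2000.0)

    def test_no_employees(self):
        _, total = labor_costs(
            [LaborLine(activity="barn", monthly_salary=4345.0, employees=0.0)]
        )
        assert total == 0.0

    def test_activities_additive(self):
        lines = [
            LaborLine(activity="a", monthly_salary=1000.0, employees=1.0),
            LaborLine(activity="b", monthly_salary=2000.0, employees=1.0),
        ]
        _, total = labor_costs(lines)
        assert total == pytest.approx(3000.0 / 4.345)


class TestUtilities:
    def test_electricity_worked_example(self):
        electricity, _ = utility_costs(
            UtilityParams(electricity_price_kwh=0.869,
                          electricity_kwh_month=1000.0)
        )
        assert electricity == pytest.approx(200.0)

    def test_share_zero_kills_both(self):
        electricity, phone = utility_costs(
            UtilityParams(electricity_price_kwh=1.0,
                          electricity_kwh_month=100.0, phone_month=50.0,
                          internet_month=50.0, share=0.0)
        )
        assert electricity == 0.0 and phone == 0.0

    def test_share_is_linear(self):
        full = utility_costs(
            UtilityParams(electricity_price_kwh=1.0,
                          electricity_kwh_month=100.0, phone_month=40.0,
                          internet_month=60.0, share=1.0)
        )
        half = utility_costs(
            UtilityParams(electricity_price_kwh=1.0,
                          electricity_kwh_month=100.0, phone_month=40.0,
                          internet_month=60.0, share=0.5)
        )
        assert half[0] == pytest.approx(full[0] / 2.0)
        assert half[1] == pytest.approx(full[1] / 2.0)


class TestFuel:
    def test_worked_example(self):
        _, total = fuel_costs(
            [FuelLine(fuel="diesel", price_per_litre=5.00,
                      litres_per_month=86.90)]
        )
        assert total == pytest.approx(100.0)

    def test_empty_register(self):
        assert fuel_costs([])[1] == 0.0

    def test_two_equal_lines_double(self):
        line = FuelLine(fuel="diesel", price_per_litre=5.0,
                        litres_per_month=86.9)
        _, total = fuel_costs([line, line])
        assert total == pytest.approx(200.0)


class TestDepreciation:
    def test_straight_line_worked_example(self):
        lines, weekly = depreciation_costs([asset()])
        # (100000 - 10000) / 10 = 9000/yr
        assert lines[0].amount == pytest.approx(9000.0 * 7.0 / 365.0)
        assert weekly == pytest.approx(172.6027, abs=5e-5)

    def test_residual_near_one_vanishes(self):
        _, weekly = depreciation_costs([asset(residual=0.999999)])
        assert weekly == pytest.approx(0.0, abs=1e-3)

    def test_zero_quantity(self):
        assert depreciation_costs([asset(qty=0.0)])[1] == 0.0

    def test_zero_life_rejected(self):
        with pytest.raises(ConfigError, match="useful life"):
            depreciation_costs([asset(life=0.0)])

    def test_value_split_invariance(self):
        whole = asset(price=100000.0, maint=0.02)
        halves = [asset(price=50000.0, maint=0.02),
                  asset(price=50000.0, maint=0.02)]
        assert depreciation_costs([whole])[1] == pytest.approx(
            depreciation_costs(halves)[1]
        )
        assert maintenance_costs([whole])[1] == pytest.approx(
            maintenance_costs(halves)[1]
        )


class TestMaintenance:
    def test_worked_example(self):
        _, weekly = maintenance_costs([asset(maint=0.02)])
        assert weekly == pytest.approx(2000.0 * 7.0 / 365.0)
        assert weekly == pytest.approx(38.3562, abs=5e-5)

    def test_zero_rate(self):
        assert maintenance_costs([asset(maint=0.0)])[1] == 0.0


class TestFinancialAndTotal:
    def test_annual_proration(self):
        assert fixed_financial(FixedTaxes(itr_annual=730.0)) == \
            pytest.approx(14.0)

    def test_total_fixed_worked_example(self):
        total = total_fixed(2000.0, 200.0, 0.0, 100.0,
                            9000.0 * 7 / 365, 2000.0 * 7 / 365, 14.0)
        assert total == pytest.approx(2524.9589, abs=5e-4)

    def test_weekly_times_phi_recovers_annual(self):
        assets = [asset(maint=0.02)]
        _, dep = depreciation_costs(assets)
        _, man = maintenance_costs(assets)
        fin = fixed_financial(FixedTaxes(itr_annual=730.0, fees_annual=70.0))
        assert dep * TIME_BASIS.phi == pytest.approx(9000.0)
        assert man * TIME_BASIS.phi == pytest.approx(2000.0)
        assert fin * TIME_BASIS.phi == pytest.approx(800.0)
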