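"""Total cost, unit costs, revenue and the profitability suite."""

import pytest

from pigcost.errors import UndefinedIndicatorError
from pigcost.indicators import (
    producer_income,
    profitability,
    revenue,
    total_cost,
    unit_costs,
)
from pigcost.models import MarketParams
from pigcost.timebase import ARROBA_KG


class TestTotalCost:
    def test_operating_plus_opportunity(self):
        cop, ct = total_cost(2495.0, 2524.9589, 212.4895)
        assert cop == pytest.approx(5019.9589)
        assert ct == pytest.approx(5232.4484)

    def test_no_opportunity(self):
        cop, ct = total_cost(100.0, 50.0, 0.0)
        assert ct == cop


class TestUnitCosts:
    def test_worked_example(self):
        per_head, per_arroba, per_kg = unit_costs(52500.0, 100.0, 115.0)
        assert per_head == pytest.approx(525.0)
        assert per_kg == pytest.approx(52500.0 / 11500.0)
        assert per_arroba == pytest.approx(52500.0 / (11500.0 / 18.75))

    def test_zero_cost_gives_zero_units(self):
        assert unit_costs(0.0, 0.0, 115.0) == (0.0, 0.0, 0.0)

    def test_empty_batch_with_cost_is_undefined(self):
        with pytest.raises(UndefinedIndicatorError):
            unit_costs(1000.0, 0.0, 115.0)

    @pytest.mark.parametrize("ct,head,kg", [(52500.0, 100.0, 115.0),
                                            (1.0, 3.0, 90.0),
                                            (1e7, 5000.0, 128.0)])
    def test_arroba_is_1875_times_kg(self, ct, head, kg):
        _, per_arroba, per_kg = unit_costs(ct, head, kg)
        assert per_arroba / per_kg == pytest.approx(ARROBA_KG)


class TestRevenue:
    MARKET = MarketParams(pig_price_kg=6.00, cull_price_kg=3.50)

    def test_batch_plus_culls(self):
        total, per_head, per_kg = revenue(
            11500.0, {"female": 1687.67}, self.MARKET, finished_head=100.0
        )
        assert total == pytest.approx(69000.0 + 1687.67 * 3.5)
        assert per_head == pytest.approx(total / 100.0)
        assert per_kg == pytest.approx(total / 11500.0)

    def test_no_culls(self):
        total, _, _ = revenue(11500.0, {}, self.MARKET, 100.0)
        assert total == pytest.approx(69000.0)

    def test_zero_prices(self):
        market = MarketParams()
        assert revenue(11500.0, {"female": 100.0}, market, 100.0) == \
            (0.0, 0.0, 0.0)

    def test_revenue_without_batch_is_undefined(self):
        with pytest.raises(UndefinedIndicatorError):
            revenue(0.0, {"female": 100.0}, self.MARKET, 0.0)


class TestProfitability:
    def test_worked_example(self):
        rs, ct = 74906.85, 52500.0
        profit, leveling, rbc, roi = profitability(rs, ct, 6.0, 115.0)
        assert profit == pytest.approx(22406.85)
        assert leveling == pytest.approx(52500.0 / (6.0 * 115.0))
        assert leveling == pytest.approx(76.087, abs=5e-4)
        assert rbc == pytest.approx(rs / ct)
        assert roi == pytest.approx(rbc - 1.0)

    def test_break_even(self):
        profit, _, rbc, roi = profitability(100.0, 100.0, 6.0, 115.0)
        assert profit == 0.0 and rbc == 1.0 and roi == 0.0

    def test_leveling_point_inversion_identity(self):
        _, leveling, _, _ = profitability(74906.85, 52500.0, 6.0, 115.0)
        assert leveling * 6.0 * 115.0 == pytest.approx(52500.0)

    def test_zero_cost_undefined(self):
        with pytest.raises(UndefinedIndicatorError):
            profitability(100.0, 0.0, 6.0, 115.0)


class TestProducerIncome:
    def test_profit_plus_opportunity_plus_family_labor(self):
        assert producer_income(22406.85, 212.4895, 1000.0) == \
            pytest.approx(23619.3395)

    def test_loss_absorbed_by_opportunity(self):
        assert producer_income(-212.4895, 212.4895, 0.0) == pytest.approx(0.0)
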