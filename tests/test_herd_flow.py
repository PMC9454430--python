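"""Weekly sow group, survival chain, batch weight, cull weight."""

import pytest
from hypothesis import given, strategies as st

from pigcost.herd import (
    batch_live_weight,
    compute_batch_flow,
    phase_populations,
    weekly_cull_weight,
    weekly_sow_group,
)
from pigcost.models import CullParams, HerdParams, PhaseDef
from pigcost.timebase import TIME_BASIS


def herd(n=1000.0, ppa=2.4, rate=0.9, born=12.0, weight=115.0,
         mortalities=(0.05, 0.02, 0.015), breeding=()):
    phases = [
        PhaseDef(category="pig", phase=f"phase{i}", mortality=m)
        for i, m in enumerate(mortalities)
    ]
    phases += [
        PhaseDef(category=c, phase=p, head_count=h) for c, p, h in breeding
    ]
    return HerdParams(
        sows_in_production=n,
        farrowings_per_sow_year=ppa,
        farrowing_rate=rate,
        born_alive_per_farrowing=born,
        finished_pig_weight_kg=weight,
        phases=phases,
    )


class TestWeeklySowGroup:
    def test_worked_example(self):
        # 1000 sows x 2.4 litters/yr x 0.90 over 365/7 weeks
        gs = weekly_sow_group(herd())
        assert gs == pytest.approx(2160.0 * 7.0 / 365.0)
        assert gs == pytest.approx(41.4247, abs=5e-5)

    def test_empty_herd(self):
        assert weekly_sow_group(herd(n=0.0)) == 0.0

    def test_identity_under_weeks_per_year(self):
        assert weekly_sow_group(herd(n=365.0 / 7.0, ppa=1.0, rate=1.0)) == \
            pytest.approx(1.0)


class TestPhasePopulations:
    def test_sequential_chain_worked_example(self):
        h = herd(mortalities=(0.05, 0.02, 0.015))
        pops, finished = phase_populations(h, weekly_group=10.0)
        assert pops[("pig", "phase0")] == pytest.approx(114.0)
        assert pops[("pig", "phase1")] == pytest.approx(111.72)
        assert finished == pytest.approx(110.0442)

    def test_lossless_chain(self):
        h = herd(mortalities=(0.0, 0.0))
        _, finished = phase_populations(h, 10.0)
        assert finished == pytest.approx(120.0)

    def test_near_total_mortality(self):
        h = herd(mortalities=(0.999,))
        _, finished = phase_populations(h, 10.0)
        assert finished == pytest.approx(120.0 * 0.001)

    def test_breeding_rows_keep_standing_counts(self):
        h = herd(breeding=(("dam", "gestation", 80.0), ("boar", "service", 2.0)))
        pops, finished = phase_populations(h, 10.0)
        assert pops[("dam", "gestation")] == 80.0
        assert pops[("boar", "service")] == 2.0
        # standing rows never alter the chain
        assert finished == pytest.approx(120.0 * 0.95 * 0.98 * 0.985)

    def test_conservation_of_head(self):
        h = herd()
        gs = weekly_sow_group(h)
        _, finished = phase_populations(h, gs)
        assert gs * h.born_alive_per_farrowing - finished >= 0.0

    @given(st.floats(min_value=0.0, max_value=0.9),
           st.floats(min_value=0.0, max_value=0.09))
    def test_raising_mortality_weakly_decreases_output(self, m, dm):
        base = phase_populations(herd(mortalities=(m, 0.02)), 10.0)[1]
        worse = phase_populations(herd(mortalities=(m + dm, 0.02)), 10.0)[1]
        assert worse <= base + 1e-12

    @given(st.floats(min_value=0.0, max_value=1e4))
    def test_flow_linear_in_sow_count(self, n):
        one = compute_batch_flow(herd(n=n))
        two = compute_batch_flow(herd(n=2.0 * n))
        assert two.weekly_group == pytest.approx(2.0 * one.weekly_group)
        assert two.finished_head == pytest.approx(2.0 * one.finished_head)
        assert two.batch_weight_kg == pytest.approx(2.0 * one.batch_weight_kg)


class TestBatchWeight:
    @pytest.mark.parametrize(
        "head,weight,expected",
        [(100.0, 115.0, 11500.0), (0.0, 115.0, 0.0), (42.5, 1.0, 42.5)],
    )
    def test_product(self, head, weight, expected):
        assert batch_live_weight(head, weight) == expected


class TestCullWeight:
    def test_worked_example(self):
        culls = [CullParams(sex="female", head_on_farm=1000.0,
                            annual_cull_rate=0.40, cull_weight_kg=220.0)]
        out = weekly_cull_weight(culls)
        assert out["female"] == pytest.approx(400.0 * 7.0 / 365.0 * 220.0)
        assert out["female"] == pytest.approx(1687.67, abs=5e-3)

    def test_zero_rate(self):
        culls = [CullParams(sex="male", head_on_farm=10.0,
                            annual_cull_rate=0.0, cull_weight_kg=250.0)]
        assert weekly_cull_weight(culls)["male"] == 0.0

    def test_two_sexes_additive(self):
        one = CullParams(sex="female", head_on_farm=100.0,
                         annual_cull_rate=0.4, cull_weight_kg=220.0)
        both = [one, CullParams(sex="male", head_on_farm=100.0,
                                annual_cull_rate=0.4, cull_weight_kg=220.0)]
        out = weekly_cull_weight(both)
        assert sum(out.values()) == pytest.approx(
            2.0 * weekly_cull_weight([one])["female"]
        )

    def test_annual_recovery(self):
        culls = [CullParams(sex="female", head_on_farm=500.0,
                            annual_cull_rate=0.45, cull_weight_kg=230.0)]
        weekly = weekly_cull_weight(culls)["female"]
        assert weekly * TIME_BASIS.phi == pytest.approx(500 * 0.45 * 230)
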