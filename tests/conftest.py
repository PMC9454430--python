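"""Shared fixtures: hand-built minimal farms and seeded synthetic ones."""

from __future__ import annotations

import pytest
from hypothesis import settings

from pigcost.models import FarmConfig, HerdParams, PhaseDef
from pigcost.synth import ScenarioSpec, generate_farm

settings.register_profile("default", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("default")


def make_minimal_farm(**overrides) -> FarmConfig:
    """A farm with a working herd and every price zero.

    The herd produces finished pigs (so unit costs are defined) but no
    register carries any money; adding a single priced line makes the
    whole ledger equal that line, which is how the unit-conversion
    ratios are isolated.
    """
    herd = HerdParams(
        sows_in_production=100.0,
        farrowings_per_sow_year=2.4,
        farrowing_rate=0.9,
        born_alive_per_farrowing=12.0,
        finished_pig_weight_kg=115.0,
        phases=[
            PhaseDef(category="piglet", phase="farrowing", mortality=0.05),
            PhaseDef(category="piglet", phase="nursery", mortality=0.02),
            PhaseDef(category="finisher", phase="finishing", mortality=0.015),
            PhaseDef(category="dam", phase="gestation", head_count=80.0),
        ],
    )
    return FarmConfig(name="minimal", herd=herd, **overrides)


@pytest.fixture
def minimal_farm() -> FarmConfig:
    return make_minimal_farm()


@pytest.fixture
def medium_farm() -> FarmConfig:
    return generate_farm(ScenarioSpec(seed=1, size_class="medium"))


@pytest.fixture(scope="session")
def farm_fleet() -> list[FarmConfig]:
    """100 seeded farms across the three size classes."""
    sizes = ("small", "medium", "large")
    return [
        generate_farm(ScenarioSpec(seed=s, size_class=sizes[s % 3]))
        for s in range(100)
    ]
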