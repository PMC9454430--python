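"""Weekly herd flow: sow group, phase populations, batch output.

The production unit of a full-cycle farm is the *weekly sow group* GS —
the females inseminated each week to keep the farrowing and weaning
schedule full. GS seeds a piglet cohort (GS x born alive) which is
carried through the ordered grow-out phases as a sequential survival
chain, each phase removing its mortality fraction. The survivors of the
final phase are the finished head of the weekly batch.

Head counts are carried as exact fractions throughout: the weekly group
is an average over the production calendar, not a census, and rounding
would bias every downstream cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import CullParams, HerdParams
from .timebase import TIME_BASIS, TimeBasis

PhaseKey = tuple[str, str]


@dataclass(frozen=True)
class BatchFlow:
    """The weekly production flow of one farm.

    Attributes
    ----------
    weekly_group:
        Females inseminated per week (GS), head, fractional.
    populations:
        Weekly head count per (category, phase) — chained counts for the
        grow-out phases, standing counts for breeding rows.
    finished_head:
        Market pigs finishing per week (end of the survival chain).
    batch_weight_kg:
        Live kilograms of market pigs sold per week.
    cull_weight_kg:
        Live kilograms of cull breeding animals sold per week, by sex.
    """

    weekly_group: float
    populations: dict[PhaseKey, float] = field(default_factory=dict)
    finished_head: float = 0.0
    batch_weight_kg: float = 0.0
    cull_weight_kg: dict[str, float] = field(default_factory=dict)

    @property
    def total_cull_kg(self) -> float:
        return sum(self.cull_weight_kg.values())


def weekly_sow_group(herd: HerdParams, tb: TimeBasis = TIME_BASIS) -> float:
    """Females inseminated per week to sustain the farrowing schedule.

    GS = N x farrowings/sow/year x farrowing rate / (weeks per year).
    """
    return (
        herd.sows_in_production
        * herd.farrowings_per_sow_year
        * herd.farrowing_rate
        / tb.phi
    )


def phase_populations(
    herd: HerdParams, weekly_group: float
) -> tuple[dict[PhaseKey, float], float]:
    """Propagate the weekly piglet cohort through the grow-out chain.

    The cohort entering the farrowing room is GS x born-alive; each
    grow-out phase, in listed order, keeps a (1 - mortality) fraction.
    Breeding rows contribute their standing head counts unchanged.

    Returns the per-(category, phase) weekly counts and the finished
    head count (survivors of the last grow-out phase).
    """
    populations: dict[PhaseKey, float] = {}
    cohort = weekly_group * herd.born_alive_per_farrowing
    finished = cohort
    for ph in herd.phases:
        if ph.is_growout:
            cohort *= 1.0 - ph.mortality
            populations[ph.key] = cohort
            finished = cohort
        else:
            populations[ph.key] = float(ph.head_count or 0.0)
    if not herd.growout_phases():
        # no grow-out rows: the cohort is sold straight off the sow
        finished = weekly_group * herd.born_alive_per_farrowing
    return populations, finished


def batch_live_weight(finished_head: float, weight_kg: float) -> float:
    """Kilograms of market pig produced per weekly batch."""
    return finished_head * weight_kg


def weekly_cull_weight(
    culls: list[CullParams], tb: TimeBasis = TIME_BASIS
) -> dict[str, float]:
    """Live kg of cull breeding stock sold per week, by sex.

    The annual cull of `head_on_farm x annual rate` animals is spread
    evenly over the weeks of the year.
    """
    out: dict[str, float] = {}
    for cull in culls:
        weekly_head = cull.head_on_farm * cull.annual_cull_rate / tb.phi
        out[cull.sex] = out.get(cull.sex, 0.0) + weekly_head * cull.cull_weight_kg
    return out


def compute_batch_flow(herd: HerdParams, tb: TimeBasis = TIME_BASIS) -> BatchFlow:
    """Assemble the complete weekly flow for a herd."""
    gs = weekly_sow_group(herd, tb)
    populations, finished = phase_populations(herd, gs)
    return BatchFlow(
        weekly_group=gs,
        populations=populations,
        finished_head=finished,
        batch_weight_kg=batch_live_weight(finished, herd.finished_pig_weight_kg),
        cull_weight_kg=weekly_cull_weight(herd.culls, tb),
    )
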