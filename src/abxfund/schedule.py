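"""Expansion of a project realization into a discrete cashflow schedule.

Valuation sums over discrete time steps.  A phase of duration d years
starting at calendar time s is expanded to ceil(d) yearly data points at
t = s, s+1, ...; the next phase starts at s + d, so steps are equidistant
within a phase but not across phase boundaries (e.g. pre-clinical of 2.5
years gives points at t = 0, 1, 2 and a following 1.75-year phase gives
points at t = 2.5 and 3.5, with the phase after that starting at 4.25).

Phase cashflows are spread evenly over the phase's steps.  Phase success
probabilities are spread as a constant per-step conditional survival
p^(1/n), so the product over a phase's steps conserves the phase's sampled
probability.  ``survive`` on each step is the probability of reaching that
step from the pre-clinical start (the ratio P0/Pt of the valuation sums);
it is 1 at t = 0 and equals P0 — the technical probability of reaching the
market — on every market step.

The 20 market years are unit steps starting at total development time.
Costs here carry no inefficiency mark-up and no prize; those belong to the
valuation perspectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .parameters import MARKET_LIFE_YEARS, AdditionalCostItem
from .sampling import PrizeDraw, ProjectRealization

__all__ = [
    "Timestep",
    "CashflowSchedule",
    "periodize",
    "allocate_additional_costs",
    "build_revenues",
    "attach_prize",
    "build_schedule",
]


@dataclass(frozen=True)
class Timestep:
    """One scheduled data point (a read-only view into the schedule)."""

    t: float  # years from pre-clinical start
    phase_id: str  # PC, P1..P4, M1..M20
    cost: float  # million USD (no inefficiency applied)
    revenue: float  # million USD
    prize: float  # million USD (0 unless the prize entry step)
    survive_to_here: float  # probability of reaching this step from t = 0


@dataclass(frozen=True)
class CashflowSchedule:
    """The periodized cashflow sequence of one project.

    Stored as parallel arrays for fast valuation; ``steps`` offers a
    per-step object view.
    """

    t: np.ndarray
    phase_ids: tuple[str, ...]
    cost: np.ndarray
    revenue: np.ndarray
    prize: np.ndarray
    survive: np.ndarray
    p_reach_market: float
    n_dev_steps: int

    @property
    def steps(self) -> list[Timestep]:
        return [
            Timestep(
                t=float(self.t[i]),
                phase_id=self.phase_ids[i],
                cost=float(self.cost[i]),
                revenue=float(self.revenue[i]),
                prize=float(self.prize[i]),
                survive_to_here=float(self.survive[i]),
            )
            for i in range(len(self.t))
        ]

    def __len__(self) -> int:
        return len(self.t)

    def phase_step_indices(self, phase_id: str) -> list[int]:
        return [i for i, p in enumerate(self.phase_ids) if p == phase_id]

    def first_step_of(self, phase_id: str) -> int:
        for i, p in enumerate(self.phase_ids):
            if p == phase_id:
                return i
        raise KeyError(f"phase {phase_id!r} not in schedule")


def _n_steps(duration: float) -> int:
    if duration <= 0:
        raise ValueError(f"phase duration must be positive, got {duration}")
    # guard against float noise turning an integer duration into an extra step
    return max(1, math.ceil(duration - 1e-9))


def build_revenues(real: ProjectRealization) -> np.ndarray:
    """Yearly revenues for market years 1..20 (million USD).

    revenue[y] = market size x market share of year y; after the sampled
    generic-entry year the revenue is cut by the sampled reduction and held
    at that reduced constant through year 20 (the share curve is already
    constant from year 10 on).
    """
    rev = np.array(
        [real.market_size * s for s in real.market_share], dtype=float
    )
    years = np.arange(1, MARKET_LIFE_YEARS + 1, dtype=float)
    rev[years > real.generic_entry_year] *= 1.0 - real.generic_reduction
    return rev


def periodize(real: ProjectRealization) -> CashflowSchedule:
    """Expand a realization into its discrete development + market steps."""
    ts: list[float] = []
    phase_ids: list[str] = []
    costs: list[float] = []
    survive: list[float] = []

    start = 0.0
    reached = 1.0  # probability of reaching the current step
    for draw in real.phase_draws:
        n = _n_steps(draw.duration)
        q = draw.prob_success ** (1.0 / n)  # constant per-step conditional survival
        for k in range(n):
            ts.append(start + k)
            phase_ids.append(draw.phase_id)
            costs.append(draw.cost / n)
            survive.append(reached * q**k)
        reached *= draw.prob_success
        start += draw.duration

    n_dev = len(ts)
    p0 = reached

    revenues = build_revenues(real)
    for y in range(MARKET_LIFE_YEARS):
        ts.append(start + y)
        phase_ids.append(f"M{y + 1}")
        costs.append(0.0)
        survive.append(p0)

    revenue = np.zeros(len(ts))
    revenue[n_dev:] = revenues

    return CashflowSchedule(
        t=np.asarray(ts, dtype=float),
        phase_ids=tuple(phase_ids),
        cost=np.asarray(costs, dtype=float),
        revenue=revenue,
        prize=np.zeros(len(ts)),
        survive=np.asarray(survive, dtype=float),
        p_reach_market=p0,
        n_dev_steps=n_dev,
    )


def allocate_additional_costs(
    schedule: CashflowSchedule,
    extra: Iterable[AdditionalCostItem],
    draws: dict[str, float],
) -> CashflowSchedule:
    """Spread each sampled extra-cost draw over the schedule.

    The item's cost is split across its allocation targets by weight, then
    evenly across that phase's steps (a market-year target such as M1 is a
    single step).  Because phases differ in length, a cost spread evenly
    across phases is generally not even across years.
    """
    cost = schedule.cost.copy()
    for item in extra:
        amount = draws[item.label]
        for phase_id, weight in item.allocation.items():
            idx = schedule.phase_step_indices(phase_id)
            if not idx:
                raise ValueError(
                    f"{item.label}: allocation target {phase_id!r} absent from schedule"
                )
            cost[idx] += weight * amount / len(idx)
    return replace(schedule, cost=cost)


def attach_prize(schedule: CashflowSchedule, prize: PrizeDraw | None) -> CashflowSchedule:
    """Place a lump-sum reward on the entry step of its phase.

    The prize pays on the first step of the named development phase, or on
    the first market year for a market entry reward.  ``None`` clears all
    prizes.
    """
    z = np.zeros(len(schedule))
    if prize is not None:
        z[schedule.first_step_of(prize.prize_phase)] = prize.prize_size
    return replace(schedule, prize=z)


def build_schedule(
    real: ProjectRealization,
    extra: Sequence[AdditionalCostItem] = (),
    prize: PrizeDraw | None = None,
) -> CashflowSchedule:
    """Periodize, allocate extra costs, and optionally attach a prize."""
    sched = periodize(real)
    if extra:
        sched = allocate_additional_costs(sched, extra, real.extra_cost_draws)
    if prize is not None:
        sched = attach_prize(sched, prize)
    return sched
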