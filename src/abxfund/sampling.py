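"""Monte Carlo sampling of project realizations and prize draws.

A *project realization* is one hypothetical antibiotic development project:
concrete phase durations, costs and success probabilities drawn from their
triangular distributions, a market trajectory, and the discount rates of
the private developer and the public benefactor.

Prize sizes are sampled log-uniformly as 10^X USD with X ~ Uniform(5, 11),
i.e. from 0.1 to 100,000 million USD, because most of the response of
go-decisions to prizes happens at small prizes.  A project never carries
more than one prize, and pre-clinical entry prizes are excluded (the
valuation viewpoint is pre-clinical, so they would escape discounting).

Reproducibility contract: one seed sequence per experiment, split
deterministically per project index, so the same seed and configuration
always yield the identical realization stream regardless of how many
indications are sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    PRIZE_PHASES,
    EconomyConfig,
    IndicationSpec,
    TriangularParam,
)

__all__ = [
    "PhaseDraw",
    "ProjectRealization",
    "PrizeDraw",
    "sample_triangular",
    "sample_project",
    "sample_prize",
    "project_rng",
]


@dataclass(frozen=True)
class PhaseDraw:
    """Concrete (duration, cost, success probability) for one phase."""

    phase_id: str
    duration: float  # years
    cost: float  # million USD
    prob_success: float  # fraction


@dataclass(frozen=True)
class ProjectRealization:
    """One sampled project, carrying every stochastic input the valuation
    consumes."""

    indication: str
    phase_draws: tuple[PhaseDraw, ...]
    market_size: float  # million USD / year
    launch_fraction: float  # position f in [0,1] between share envelopes
    market_share: tuple[float, ...]  # 20 yearly fractions
    generic_entry_year: float  # real years after market entry
    generic_reduction: float  # fraction
    private_rate: float  # r, fraction / year
    social_rate: float  # r', fraction / year
    extra_cost_draws: dict[str, float]  # label -> sampled million USD

    @property
    def p_reach_market(self) -> float:
        """Technical probability of reaching the market: the product of the
        per-phase success-probability draws."""
        p = 1.0
        for d in self.phase_draws:
            p *= d.prob_success
        return p

    @property
    def total_development_years(self) -> float:
        return sum(d.duration for d in self.phase_draws)


@dataclass(frozen=True)
class PrizeDraw:
    """A lump-sum entry reward: which phase it pays on entry to, and how
    much (million USD)."""

    prize_phase: str
    prize_size: float

    def __post_init__(self) -> None:
        if self.prize_phase not in PRIZE_PHASES:
            raise ValueError(f"prize_phase must be one of {PRIZE_PHASES}")
        if self.prize_size <= 0:
            raise ValueError("prize_size must be > 0")


def sample_triangular(p: TriangularParam, rng: np.random.Generator) -> float:
    """Draw once from triangular(min, mode, max) by inverse CDF.

    A degenerate triple returns its constant.  Exactly one uniform variate
    is consumed either way, which keeps the draw stream stable when some
    parameters are fixed.
    """
    u = rng.random()
    if p.is_degenerate:
        return p.min
    span = p.max - p.min
    c = (p.mode - p.min) / span
    if u < c:
        return p.min + math.sqrt(u * span * (p.mode - p.min))
    return p.max - math.sqrt((1.0 - u) * span * (p.max - p.mode))


def sample_project(
    spec: IndicationSpec, cfg: EconomyConfig, rng: np.random.Generator
) -> ProjectRealization:
    """Draw one complete project realization for one indication.

    The market-share curve is not sampled per year.  Instead the
    launch-success draw is rescaled to a single fraction
    f = (draw - min) / (max - min), and share[y] =
    lower[y] + f * (upper[y] - lower[y]) for every year, so the position
    between the envelopes is constant across years and the curve is
    non-decreasing up to the peak-sales year.
    """
    market = spec.market

    phase_draws = tuple(
        PhaseDraw(
            phase_id=ph.phase_id,
            duration=sample_triangular(ph.time, rng),
            cost=sample_triangular(ph.cost, rng),
            prob_success=sample_triangular(ph.prob_success, rng),
        )
        for ph in spec.phases
    )

    size = rng.uniform(market.market_size.min, market.market_size.max)

    launch = sample_triangular(market.launch_success, rng)
    f = (launch - market.launch_success.min) / (
        market.launch_success.max - market.launch_success.min
    )
    share = tuple(
        lo + f * (hi - lo) for lo, hi in zip(market.share_lower, market.share_upper)
    )

    generic_year = sample_triangular(market.generic_entry_year, rng)
    generic_red = sample_triangular(market.generic_revenue_reduction, rng)

    r = sample_triangular(cfg.private_discount, rng)
    r_social = rng.uniform(cfg.social_discount_low, cfg.social_discount_high)

    extras = {
        item.label: sample_triangular(item.cost, rng) for item in spec.extra_costs
    }

    return ProjectRealization(
        indication=spec.indication,
        phase_draws=phase_draws,
        market_size=size,
        launch_fraction=f,
        market_share=share,
        generic_entry_year=generic_year,
        generic_reduction=generic_red,
        private_rate=r,
        social_rate=r_social,
        extra_cost_draws=extras,
    )


def sample_prize(
    rng: np.random.Generator, prize_phase: str | None = None
) -> PrizeDraw:
    """Draw one prize: size = 10^X USD, X ~ Uniform(5, 11), reported in
    million USD (10^(X-6)); the phase is drawn uniformly from P1..P4, M1
    unless fixed."""
    x = rng.uniform(5.0, 11.0)
    size = 10.0 ** (x - 6.0)  # USD -> million USD
    if prize_phase is None:
        prize_phase = PRIZE_PHASES[rng.integers(len(PRIZE_PHASES))]
    return PrizeDraw(prize_phase=prize_phase, prize_size=size)


def project_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    """Generator for project ``index`` of experiment stream ``stream``.

    Splitting by (seed, stream, index) makes every project's draws
    independent of how many projects or indications precede it.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))
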