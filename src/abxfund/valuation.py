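"""Four-perspective expected net present value of a cashflow schedule.

Every perspective is the same risk-adjusted discounted sum

    sum_t  cashflow_t * survive_t / (1 + rate)^t

over the schedule's steps, with real-valued exponents t (the periodization
produces fractional times such as 2.5), differing only in which cashflows
enter and at whose discount rate:

* private           (R_t - C_t)        at the developer's rate r
* intervened        (R_t - C_t + Z_t)  at r — the developer's view of a
                                        publicly announced prize Z
* indirect          (-Z_t)             at the benefactor's social rate r'
                                        — the expected cost of the prize
* direct            (-(1+i) C_t)       at r' — paying development at-cost,
                                        inflated by the inefficiency i

Indirect and direct values are always <= 0: they see only costs.  A
developer reaches a go-decision when its (intervened) private value is
non-negative.  Dividing a benefactor cost by P0, the technical probability
of reaching market, converts expected cost per go-decision into expected
cost per observed market approval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import CashflowSchedule

__all__ = [
    "EnpvResult",
    "enpv_private",
    "enpv_intervened",
    "enpv_indirect",
    "enpv_direct",
    "per_market_approval",
    "cost_savings",
    "evaluate",
]


@dataclass(frozen=True)
class EnpvResult:
    """The four perspective valuations of one realization (million USD)."""

    private: float
    intervened_private: float
    indirect: float
    direct: float
    p_reach_market: float

    @property
    def go_without(self) -> bool:
        return self.private >= 0.0

    @property
    def go_with(self) -> bool:
        return self.intervened_private >= 0.0

    @property
    def improvement(self) -> float:
        """Gain in the developer's valuation caused by the prize; > 0 for
        any positive prize."""
        return self.intervened_private - self.private


def _check_rate(rate: float) -> None:
    if rate <= -1.0:
        raise ValueError(f"discount rate must be > -1, got {rate}")


def _npv(s: CashflowSchedule, cashflow: np.ndarray, rate: float) -> float:
    _check_rate(rate)
    return float(np.sum(cashflow * s.survive / (1.0 + rate) ** s.t))


def enpv_private(s: CashflowSchedule, r: float) -> float:
    """Developer's valuation: revenues minus costs at the private rate."""
    return _npv(s, s.revenue - s.cost, r)


def enpv_intervened(s: CashflowSchedule, r: float) -> float:
    """Developer's valuation including the attached prize."""
    return _npv(s, s.revenue - s.cost + s.prize, r)


def enpv_indirect(s: CashflowSchedule, r_social: float) -> float:
    """Benefactor's expected cost of the prize (<= 0; 0 without a prize)."""
    return _npv(s, -s.prize, r_social)


def enpv_direct(s: CashflowSchedule, r_social: float, inefficiency: float = 0.0) -> float:
    """Benefactor's expected cost of at-cost funding, inflated by (1+i)."""
    if inefficiency < 0:
        raise ValueError(f"inefficiency must be >= 0, got {inefficiency}")
    return _npv(s, -(1.0 + inefficiency) * s.cost, r_social)


def per_market_approval(value: float, s: CashflowSchedule) -> float:
    """Rescale a valuation from per-project to per observed market approval
    by dividing by P0."""
    if s.p_reach_market <= 0:
        raise ValueError("p_reach_market must be > 0")
    return value / s.p_reach_market


def cost_savings(res: EnpvResult, s: CashflowSchedule) -> float:
    """Cost savings of direct funding, per market approval (million USD).

    Defined as direct minus indirect expected cost, each divided by P0;
    positive means direct funding is cheaper.  Only meaningful for
    stimulated projects (intervened private value >= 0) — an ineffective
    prize is never paid out, so calling this on a non-stimulated sample
    signals a filtering bug upstream.
    """
    if not res.go_with:
        raise ValueError("cost_savings is undefined for non-stimulated samples")
    return per_market_approval(res.direct, s) - per_market_approval(res.indirect, s)


def evaluate(
    s: CashflowSchedule,
    r: float,
    r_social: float,
    inefficiency: float = 0.0,
) -> EnpvResult:
    """All four perspectives of one schedule in a single pass."""
    _check_rate(r)
    _check_rate(r_social)
    private_df = s.survive / (1.0 + r) ** s.t
    social_df = s.survive / (1.0 + r_social) ** s.t
    net = s.revenue - s.cost
    private = float(np.sum(net * private_df))
    intervened = float(np.sum((net + s.prize) * private_df))
    indirect = float(np.sum(-s.prize * social_df))
    direct = float(np.sum(-(1.0 + inefficiency) * s.cost * social_df))
    return EnpvResult(
        private=private,
        intervened_private=intervened,
        indirect=indirect,
        direct=direct,
        p_reach_market=s.p_reach_market,
    )
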