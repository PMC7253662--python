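import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abxfund.sampling import PrizeDraw
from abxfund.schedule import (
    allocate_additional_costs,
    attach_prize,
    build_revenues,
    build_schedule,
    periodize,
)

from conftest import make_realization


class TestPeriodize:
    def test_worked_example_step_times(self, toy_real):
        # PC of 2.5y -> points at 0, 1, 2; P1 of 1.75y -> 2.5, 3.5; P2 starts 4.25
        s = periodize(toy_real)
        assert list(s.t[:5]) == [0.0, 1.0, 2.0, 2.5, 3.5]
        assert s.phase_ids[:5] == ("PC", "PC", "PC", "P1", "P1")
        assert s.t[s.first_step_of("P2")] == pytest.approx(4.25)

    def test_step_counts(self, toy_real):
        s = periodize(toy_real)
        n_dev = sum(math.ceil(d.duration) for d in toy_real.phase_draws)
        assert s.n_dev_steps == n_dev
        assert len(s) == n_dev + 20

    def test_survival_split_is_geometric(self):
        real = make_realization(durations=(2.0, 1.0, 1.0, 1.0, 1.0), probs=(0.5, 1, 1, 1, 1))
        s = periodize(real)
        # phase with prob 0.5 over 2 steps: per-step conditional sqrt(0.5)
        assert s.survive[0] == 1.0
        assert s.survive[1] == pytest.approx(math.sqrt(0.5))
        assert s.survive[2] == pytest.approx(0.5)  # next phase entry

    def test_survival_monotone_and_market_at_p0(self, toy_real):
        s = periodize(toy_real)
        assert np.all(np.diff(s.survive) <= 1e-12)
        p0 = np.prod([d.prob_success for d in toy_real.phase_draws])
        assert s.p_reach_market == pytest.approx(p0)
        assert np.allclose(s.survive[s.n_dev_steps :], p0)

    def test_single_step_phase(self):
        real = make_realization(durations=(1.0, 1.0, 1.0, 1.0, 1.0), costs=(10, 0, 0, 0, 0))
        s = periodize(real)
        assert s.t[0] == 0.0 and s.cost[0] == pytest.approx(10.0)

    def test_nonpositive_duration_rejected(self):
        real = make_realization(durations=(0.0, 1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="duration"):
            periodize(real)

    @settings(max_examples=40, derandomize=True)
    @given(
        durations=st.tuples(*[st.floats(0.1, 6.0)] * 5),
        probs=st.tuples(*[st.floats(0.05, 1.0)] * 5),
    )
    def test_survival_product_conserved(self, durations, probs):
        real = make_realization(durations=durations, probs=probs)
        s = periodize(real)
        # product of per-step conditional survivals over development = P0
        dev = s.survive[: s.n_dev_steps]
        last_cond = s.p_reach_market / dev[-1]
        assert dev[0] == pytest.approx(1.0)
        assert last_cond * dev[-1] / dev[0] == pytest.approx(s.p_reach_market)
        conds = np.append(dev[1:] / dev[:-1], last_cond)
        assert np.prod(conds) == pytest.approx(s.p_reach_market, rel=1e-9)


class TestAdditionalCosts:
    def test_spread_across_phases_and_market_years(self, specs):
        draws = {
            "Sample prep.": 2.7,
            "Process dev.": 26.8,
            "Plant design": 13.4,
            "Plant build": 83.0,
            "Non-clinical": 3.7,
            "PAS": 10.0,
        }
        real = make_realization(extra_cost_draws=draws)
        base = periodize(real)
        s = allocate_additional_costs(base, specs["ABOM"].extra_costs, draws)
        added = s.cost - base.cost

        def phase_total(pid):
            return added[s.phase_step_indices(pid)].sum()

        # sample prep 2.7 over P1, P2, P3 -> 0.9 each
        assert phase_total("P1") == pytest.approx(0.9 + 26.8 / 2)
        # plant design 75%/25% over P3/P4
        assert phase_total("P3") == pytest.approx(0.9 + 13.4 * 0.75 + 3.7 / 3)
        assert phase_total("P4") == pytest.approx(13.4 * 0.25 + 83.0 + 3.7 / 3)
        # PAS evenly over exactly the first three market years
        for y in (1, 2, 3):
            assert phase_total(f"M{y}") == pytest.approx(10.0 / 3)
        assert phase_total("M4") == 0.0

    def test_total_cost_conservation(self, specs):
        draws = {it.label: it.cost.mode for it in specs["CUTI"].extra_costs}
        real = make_realization(extra_cost_draws=draws)
        s = allocate_additional_costs(periodize(real), specs["CUTI"].extra_costs, draws)
        expected = sum(d.cost for d in real.phase_draws) + sum(draws.values())
        assert s.cost.sum() == pytest.approx(expected, rel=1e-12)

    def test_missing_phase_rejected(self, specs):
        real = make_realization(extra_cost_draws={"PAS": 10.0})
        s = periodize(real)
        bad = [it for it in specs["ABOM"].extra_costs if it.label == "PAS"]
        trimmed = s.__class__(
            t=s.t[: s.n_dev_steps],
            phase_ids=s.phase_ids[: s.n_dev_steps],
            cost=s.cost[: s.n_dev_steps],
            revenue=s.revenue[: s.n_dev_steps],
            prize=s.prize[: s.n_dev_steps],
            survive=s.survive[: s.n_dev_steps],
            p_reach_market=s.p_reach_market,
            n_dev_steps=s.n_dev_steps,
        )
        with pytest.raises(ValueError, match="absent"):
            allocate_additional_costs(trimmed, bad, {"PAS": 10.0})


class TestRevenues:
    def test_hand_product_of_size_and_share(self):
        real = make_realization(market_size=2720.0, launch_fraction=0.0)
        rev = build_revenues(real)
        assert rev[0] == pytest.approx(2720 * 0.0005)  # = 1.36

    def test_generic_entry_reduces_to_constant(self):
        real = make_realization(generic_entry_year=12.0, generic_reduction=0.5)
        rev = build_revenues(real)
        assert np.allclose(rev[10:12], rev[9])  # years 11-12 at peak
        assert np.allclose(rev[12:], 0.5 * rev[9])  # years 13-20 halved

    def test_zero_reduction_is_identity(self):
        a = build_revenues(make_realization(generic_reduction=0.0))
        b = build_revenues(make_realization(generic_reduction=0.7))
        assert np.allclose(a[:10], b[:10])
        assert a[19] > b[19]

    def test_fractional_entry_year(self):
        real = make_realization(generic_entry_year=10.3, generic_reduction=0.25)
        rev = build_revenues(real)
        # reduction applies from the first market year strictly after entry
        assert rev[9] == pytest.approx(real.market_size * real.market_share[9])
        assert rev[10] == pytest.approx(0.75 * rev[9])


class TestAttachPrize:
    def test_prize_on_phase_entry_step(self, toy_real):
        s = attach_prize(periodize(toy_real), PrizeDraw("P1", 100.0))
        i = s.first_step_of("P1")
        assert s.t[i] == pytest.approx(2.5)  # PC duration
        assert s.prize[i] == 100.0 and s.prize.sum() == 100.0

    def test_market_entry_prize_survives_at_p0(self, toy_real):
        s = attach_prize(periodize(toy_real), PrizeDraw("M1", 50.0))
        i = s.first_step_of("M1")
        assert s.prize[i] == 50.0
        assert s.survive[i] == pytest.approx(s.p_reach_market)

    def test_none_clears_prizes(self, toy_real):
        s = attach_prize(periodize(toy_real), PrizeDraw("P2", 9.0))
        assert attach_prize(s, None).prize.sum() == 0.0

    def test_build_schedule_composes(self, specs, toy_real):
        draws = {it.label: it.cost.mode for it in specs["ABOM"].extra_costs}
        real = make_realization(extra_cost_draws=draws)
        s = build_schedule(real, extra=specs["ABOM"].extra_costs, prize=PrizeDraw("M1", 10.0))
        assert s.prize.sum() == 10.0
        assert s.cost.sum() > periodize(real).cost.sum()
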