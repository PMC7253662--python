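import numpy as np
import pytest

from abxfund import EconomyConfig, load_parameters
from abxfund.sampling import PhaseDraw, ProjectRealization


@pytest.fixture(scope="session")
def specs():
    return load_parameters()


@pytest.fixture(scope="session")
def cfg():
    return EconomyConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_realization(
    *,
    indication="ABOM",
    durations=(2.5, 1.75, 1.0, 2.0, 0.75),
    costs=(21.1, 9.7, 9.2, 41.7, 1.9588),
    probs=(0.352, 0.33, 0.5, 0.67, 0.85),
    market_size=2720.0,
    launch_fraction=0.0,
    generic_entry_year=12.0,
    generic_reduction=0.5,
    private_rate=0.11,
    social_rate=0.04,
    extra_cost_draws=None,
    share_lower=None,
    share_upper=None,
):
    """Hand-built project realization for deterministic schedule tests."""
    lower = share_lower or (
        [0.0005, 0.0087, 0.0157, 0.0257, 0.0392, 0.0579, 0.0752, 0.0852, 0.1010]
        + [0.1227] * 11
    )
    upper = share_upper or (
        [0.0011, 0.0191, 0.0347, 0.0568, 0.0864, 0.1277, 0.1659, 0.1880, 0.2230]
        + [0.2708] * 11
    )
    share = tuple(
        lo + launch_fraction * (hi - lo) for lo, hi in zip(lower, upper)
    )
    phases = tuple(
        PhaseDraw(pid, d, c, p)
        for pid, d, c, p in zip(("PC", "P1", "P2", "P3", "P4"), durations, costs, probs)
    )
    return ProjectRealization(
        indication=indication,
        phase_draws=phases,
        market_size=market_size,
        launch_fraction=launch_fraction,
        market_share=share,
        generic_entry_year=generic_entry_year,
        generic_reduction=generic_reduction,
        private_rate=private_rate,
        social_rate=social_rate,
        extra_cost_draws=extra_cost_draws or {},
    )


@pytest.fixture()
def toy_real():
    return make_realization()
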