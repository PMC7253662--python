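"""Optional figure helpers (requires matplotlib).

Quick visual analogues of the pipeline's main outputs: the prize-response
sigmoids, the cost-savings heatmap with its zero frontier, and the
funding-cost distributions.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .experiments import FrontierFit, GridCell, ScenarioResult, grid_to_frame
from .incentive import IncentiveResponseFit, predict_pgo
from .parameters import PRIZE_PHASES


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_pgo_curves(
    pgo_fits: Mapping[tuple[str, str], IncentiveResponseFit],
    indication: str,
    ax=None,
):
    """Fitted conditional go-probability versus prize size (log scale)."""
    plt = _plt()
    ax = ax or plt.gca()
    grid = 10.0 ** np.linspace(-1.0, 5.0, 200)
    for phase in PRIZE_PHASES:
        fit = pgo_fits[(indication, phase)]
        ax.plot(grid, [predict_pgo(fit, z) for z in grid], label=phase)
    ax.set_xscale("log")
    ax.set_xlabel("prize size (million USD)")
    ax.set_ylabel("P(go)")
    ax.set_title(indication)
    ax.legend()
    return ax


def plot_savings_heatmap(
    cells: Sequence[GridCell],
    indication: str,
    prize_phase: str,
    frontier: FrontierFit | None = None,
    ax=None,
):
    """Mean cost savings of direct funding over the P(go) x inefficiency
    grid, with the zero-savings frontier overlaid."""
    plt = _plt()
    ax = ax or plt.gca()
    df = grid_to_frame(cells)
    df = df[(df.indication == indication) & (df.prize_phase == prize_phase)]
    pivot = df.pivot(index="target_pgo", columns="inefficiency",
                     values="mean_cost_savings")
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.values,
                         cmap="RdBu", shading="nearest")
    plt.colorbar(mesh, ax=ax, label="mean savings of direct funding (MUSD/approval)")
    if frontier is not None and not frontier.flagged:
        xs = np.linspace(df.inefficiency.min(), df.inefficiency.max(), 100)
        ax.plot(xs, [frontier.pgo_at(x) for x in xs], color="white", lw=2)
    ax.set_xlabel("inefficiency i")
    ax.set_ylabel("target P(go)")
    ax.set_title(f"{indication} / {prize_phase}")
    return ax


def plot_cost_distributions(res: ScenarioResult, indication: str, ax=None):
    """Per-approval funding-cost distributions by prize phase."""
    plt = _plt()
    ax = ax or plt.gca()
    d = res.distributions[res.distributions.Indication == indication]
    data = [d[d.prize_phase == ph]["indirect_cost_per_approval"] for ph in PRIZE_PHASES]
    ax.boxplot(data, tick_labels=list(PRIZE_PHASES), showfliers=False)
    direct = d["direct_cost_per_approval"].median()
    ax.axhline(direct, ls="--", color="k", label="direct funding (median)")
    ax.set_ylabel("cost per market approval (million USD)")
    ax.set_title(indication)
    ax.legend()
    return ax
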