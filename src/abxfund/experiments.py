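"""The three simulation campaigns.

* **baseline** — 2,000 projects per indication: baseline go/no-decision
  ratios, the prize-response fits per indication x prize phase, and the
  prizes that hit a target conditional go-probability (default 90%).
* **grid** — a sweep over target P(go) x benefactor inefficiency (40 x 41
  cells by default, 10 fresh projects each) producing the mean cost
  savings of direct funding per cell, plus the zero-savings frontier
  fitted as a quadratic in inefficiency.
* **scenario** — 1,000 projects per indication at inefficiency 50% and
  prizes sized for P(go) = 90%: mean cost savings per market approval and
  the per-sample funding-cost distributions.

Cost savings of direct funding are computed per observed market approval:
(direct - indirect expected cost) / P0, on the subset of projects actually
stimulated by the prize (post-prize developer valuation >= 0); projects an
intervention fails to stimulate never cost the benefactor anything.

Each campaign draws from its own deterministic stream family, split per
project index, so identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .incentive import IncentiveResponseFit, fit_improvement, fit_pgo, solve_prize
from .parameters import (
    INDICATIONS,
    PRIZE_PHASES,
    EconomyConfig,
    IndicationSpec,
)
from .sampling import ProjectRealization, project_rng, sample_project
from .schedule import build_schedule
from .valuation import evaluate

__all__ = [
    "ProjectEvaluation",
    "BaselineResult",
    "GridCell",
    "FrontierFit",
    "ScenarioResult",
    "evaluate_project",
    "simulate_batch",
    "run_baseline",
    "run_grid",
    "fit_frontier",
    "run_scenario",
]

# stream families (first element of the per-project spawn key)
_BASELINE_STREAM = 0
_SCENARIO_STREAM = 100
_GRID_STREAM = 1000


@dataclass(frozen=True)
class ProjectEvaluation:
    """One project's valuation summary, pre-computed so that any prize
    (phase, size) can be priced without rebuilding the schedule.

    A lump-sum prize Z at phase ``ph`` enters each perspective linearly
    through the discount weight of that phase's entry step, so

        intervened = private + Z * prize_weight_private[ph]
        indirect   = -Z * prize_weight_social[ph]
        direct(i)  = (1 + i) * direct_base
    """

    indication: str
    private: float
    direct_base: float  # direct ENPV at inefficiency 0 (<= 0)
    p_reach_market: float
    prize_weight_private: Mapping[str, float]  # survive / (1+r)^t at entry step
    prize_weight_social: Mapping[str, float]
    prize_size: float  # the project's log-uniform prize draw (million USD)

    @property
    def go_without(self) -> bool:
        return self.private >= 0.0

    def intervened(self, phase: str, prize_size: float) -> float:
        return self.private + prize_size * self.prize_weight_private[phase]

    def improvement(self, phase: str, prize_size: float) -> float:
        return prize_size * self.prize_weight_private[phase]

    def indirect(self, phase: str, prize_size: float) -> float:
        return -prize_size * self.prize_weight_social[phase]

    def direct(self, inefficiency: float) -> float:
        return (1.0 + inefficiency) * self.direct_base

    def cost_savings(self, phase: str, prize_size: float, inefficiency: float) -> float:
        return (
            self.direct(inefficiency) - self.indirect(phase, prize_size)
        ) / self.p_reach_market


def evaluate_project(
    real: ProjectRealization, spec: IndicationSpec, prize_size: float
) -> ProjectEvaluation:
    """Build the schedule once and summarize everything prize pricing needs."""
    sched = build_schedule(real, extra=spec.extra_costs)
    base = evaluate(sched, r=real.private_rate, r_social=real.social_rate)
    wp: dict[str, float] = {}
    ws: dict[str, float] = {}
    for phase in PRIZE_PHASES:
        idx = sched.first_step_of(phase)
        t = sched.t[idx]
        surv = sched.survive[idx]
        wp[phase] = float(surv / (1.0 + real.private_rate) ** t)
        ws[phase] = float(surv / (1.0 + real.social_rate) ** t)
    return ProjectEvaluation(
        indication=real.indication,
        private=base.private,
        direct_base=base.direct,
        p_reach_market=sched.p_reach_market,
        prize_weight_private=wp,
        prize_weight_social=ws,
        prize_size=prize_size,
    )


def simulate_batch(
    spec: IndicationSpec,
    cfg: EconomyConfig,
    seed: int,
    stream: int,
    n: int,
) -> list[ProjectEvaluation]:
    """Sample and evaluate ``n`` projects from one deterministic stream.

    Each project also draws its own log-uniform prize size (one draw per
    project; treatments at different phases reuse the same size, a project
    never carries two prizes at once).
    """
    out = []
    for i in range(n):
        rng = project_rng(seed, stream, i)
        real = sample_project(spec, cfg, rng)
        prize_size = 10.0 ** (rng.uniform(5.0, 11.0) - 6.0)  # million USD
        out.append(evaluate_project(real, spec, prize_size))
    return out


# ---------------------------------------------------------------------------
# baseline


@dataclass(frozen=True)
class BaselineResult:
    """Baseline decision ratios, response fits, and solved prizes."""

    go_ratios: pd.DataFrame  # index indication; columns Go, No (fractions); n
    improvement_fits: Mapping[tuple[str, str], IncentiveResponseFit]
    pgo_fits: Mapping[tuple[str, str], IncentiveResponseFit]
    prizes: pd.DataFrame  # index indication; columns P1..M1 (million USD)
    target_pgo: float
    n_samples: int
    seed: int

    def prize(self, indication: str, phase: str) -> float:
        return float(self.prizes.loc[indication, phase])


def run_baseline(
    specs: Mapping[str, IndicationSpec],
    n_samples: int = 2000,
    seed: int = 0,
    target_pgo: float = 0.9,
    cfg: EconomyConfig | None = None,
) -> BaselineResult:
    """Baseline campaign: decision ratios, response fits, solved prizes."""
    cfg = cfg or EconomyConfig(seed=seed, n_samples=n_samples)
    go_rows = []
    imp_fits: dict[tuple[str, str], IncentiveResponseFit] = {}
    pgo_fits: dict[tuple[str, str], IncentiveResponseFit] = {}
    prize_rows = []
    for ind_idx, ind in enumerate(INDICATIONS):
        evs = simulate_batch(
            specs[ind], cfg, seed, _BASELINE_STREAM + ind_idx, n_samples
        )
        n_go = sum(e.go_without for e in evs)
        go_rows.append(
            {"Indication": ind, "Go": n_go / n_samples, "No": 1.0 - n_go / n_samples, "n": n_samples}
        )
        prize_row: dict[str, object] = {"Indication": ind}
        for phase in PRIZE_PHASES:
            imp = [(e.prize_size, e.improvement(phase, e.prize_size)) for e in evs]
            imp_fits[(ind, phase)] = fit_improvement(imp, ind, phase)
            nogo = [
                (e.prize_size, e.intervened(phase, e.prize_size) >= 0.0)
                for e in evs
                if not e.go_without
            ]
            pfit = fit_pgo(nogo, ind, phase)
            pgo_fits[(ind, phase)] = pfit
            prize_row[phase] = solve_prize(pfit, target_pgo)
        prize_rows.append(prize_row)

    go_df = pd.DataFrame(go_rows).set_index("Indication")
    prize_df = pd.DataFrame(prize_rows).set_index("Indication")
    return BaselineResult(
        go_ratios=go_df,
        improvement_fits=imp_fits,
        pgo_fits=pgo_fits,
        prizes=prize_df,
        target_pgo=target_pgo,
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# grid


@dataclass(frozen=True)
class GridCell:
    """Mean cost savings of direct funding in one sweep cell."""

    indication: str
    prize_phase: str
    target_pgo: float
    inefficiency: float
    prize_size: float  # million USD, solved from the P(go) fit
    mean_cost_savings: float  # million USD per market approval; NaN if empty
    n_effective: int  # stimulated samples retained


def default_pgo_grid(n: int = 40) -> np.ndarray:
    return np.linspace(0.5, 0.9875, n)


def default_inefficiency_grid(n: int = 41) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def run_grid(
    specs: Mapping[str, IndicationSpec],
    baseline: BaselineResult,
    pgo_grid: Sequence[float] | None = None,
    inefficiency_grid: Sequence[float] | None = None,
    n_per_cell: int = 10,
    seed: int = 0,
    indications: Sequence[str] = INDICATIONS,
    prize_phases: Sequence[str] = PRIZE_PHASES,
    cfg: EconomyConfig | None = None,
) -> list[GridCell]:
    """Sweep target P(go) x inefficiency, redrawing ``n_per_cell`` projects
    per cell from a cell-indexed stream.

    Prizes are solved from the baseline P(go) fits, not refitted per cell.
    Cells in which no sample is stimulated are recorded as empty (NaN
    savings) rather than zero.
    """
    pgo_grid = default_pgo_grid() if pgo_grid is None else np.asarray(pgo_grid, float)
    ineff_grid = (
        default_inefficiency_grid()
        if inefficiency_grid is None
        else np.asarray(inefficiency_grid, float)
    )
    cfg = cfg or EconomyConfig(seed=seed)
    cells: list[GridCell] = []
    cell_counter = 0
    for ind in indications:
        ind_idx = INDICATIONS.index(ind)
        for phase in prize_phases:
            pfit = baseline.pgo_fits[(ind, phase)]
            for pgo in pgo_grid:
                prize = solve_prize(pfit, float(pgo))
                for ineff in ineff_grid:
                    stream = _GRID_STREAM + cell_counter
                    cell_counter += 1
                    evs = simulate_batch(
                        specs[ind], cfg, seed, stream, n_per_cell
                    )
                    kept = [
                        e for e in evs if e.intervened(phase, prize) >= 0.0
                    ]
                    if kept:
                        savings = float(
                            np.mean(
                                [e.cost_savings(phase, prize, float(ineff)) for e in kept]
                            )
                        )
                    else:
                        savings = float("nan")
                    cells.append(
                        GridCell(
                            indication=ind,
                            prize_phase=phase,
                            target_pgo=float(pgo),
                            inefficiency=float(ineff),
                            prize_size=prize,
                            mean_cost_savings=savings,
                            n_effective=len(kept),
                        )
                    )
    return cells


def grid_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


@dataclass(frozen=True)
class FrontierFit:
    """Quadratic zero-savings frontier: the P(go) at which indirect and
    direct funding cost the same, as a function of inefficiency.

    pgo(i) = a * i**2 + b * i + c, fitted through the grid cells closest
    to zero savings in each inefficiency column.
    """

    indication: str
    prize_phase: str
    a: float
    b: float
    c: float
    n_points: int
    flagged: bool = False
    points: tuple[tuple[float, float], ...] = field(default=())

    def pgo_at(self, inefficiency: float) -> float:
        return self.a * inefficiency**2 + self.b * inefficiency + self.c


def fit_frontier(cells: Sequence[GridCell]) -> dict[tuple[str, str], FrontierFit]:
    """Fit the zero-crossing frontier per indication x prize phase.

    For each inefficiency column that contains both signs of savings, the
    cell with the smallest |mean savings| marks the crossing; a quadratic
    of target P(go) on inefficiency is fitted through those points.
    Combinations with fewer than 3 crossing columns are flagged and carry
    NaN coefficients.
    """
    df = grid_to_frame(cells)
    fits: dict[tuple[str, str], FrontierFit] = {}
    for (ind, phase), sub in df.groupby(["indication", "prize_phase"], sort=False):
        pts: list[tuple[float, float]] = []
        for ineff, col in sub.groupby("inefficiency"):
            col = col.dropna(subset=["mean_cost_savings"])
            if col.empty:
                continue
            s = col["mean_cost_savings"]
            if s.min() >= 0 or s.max() <= 0:
                continue  # no sign change: no crossing in this column
            best = col.loc[s.abs().idxmin()]
            pts.append((float(ineff), float(best["target_pgo"])))
        if len(pts) < 3:
            fits[(ind, phase)] = FrontierFit(
                indication=ind, prize_phase=phase,
                a=float("nan"), b=float("nan"), c=float("nan"),
                n_points=len(pts), flagged=True, points=tuple(pts),
            )
            continue
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        a, b, c = np.polyfit(xs, ys, 2)
        fits[(ind, phase)] = FrontierFit(
            indication=ind, prize_phase=phase,
            a=float(a), b=float(b), c=float(c),
            n_points=len(pts), points=tuple(pts),
        )
    return fits


# ---------------------------------------------------------------------------
# scenario


@dataclass(frozen=True)
class ScenarioResult:
    """Mean cost savings and funding-cost distributions in one scenario."""

    mean_savings: pd.DataFrame  # index indication; columns P1..M1 (million USD)
    distributions: pd.DataFrame  # per retained sample: costs per approval
    prizes: pd.DataFrame  # prize schedule used (million USD)
    inefficiency: float
    target_pgo: float
    n_samples: int
    seed: int


def run_scenario(
    specs: Mapping[str, IndicationSpec],
    baseline: BaselineResult | None = None,
    n_samples: int = 1000,
    inefficiency: float = 0.5,
    target_pgo: float = 0.9,
    seed: int = 0,
    cfg: EconomyConfig | None = None,
    prizes: pd.DataFrame | None = None,
) -> ScenarioResult:
    """Scenario campaign: fixed inefficiency, prizes sized per indication
    and phase to yield the target P(go).

    The prize schedule can be given directly (``prizes``, rows =
    indications, columns = prize phases; e.g. the packaged reference
    schedule) or is solved from the baseline fits.  The same fresh project
    batch per indication is priced under all five prize phases; the
    retained (stimulated) subset therefore varies by phase while the
    underlying projects do not.
    """
    if prizes is None and baseline is None:
        raise ValueError("provide either a baseline result or a prize schedule")
    cfg = cfg or EconomyConfig(seed=seed, inefficiency=inefficiency)
    rows = []
    dist_rows = []
    used_prizes = pd.DataFrame(
        index=list(INDICATIONS), columns=list(PRIZE_PHASES), dtype=float
    )
    used_prizes.index.name = "Indication"
    for ind_idx, ind in enumerate(INDICATIONS):
        evs = simulate_batch(
            specs[ind], cfg, seed, _SCENARIO_STREAM + ind_idx, n_samples
        )
        row: dict[str, object] = {"Indication": ind}
        for phase in PRIZE_PHASES:
            if prizes is not None:
                prize = float(prizes.loc[ind, phase])
            elif target_pgo != baseline.target_pgo:
                prize = solve_prize(baseline.pgo_fits[(ind, phase)], target_pgo)
            else:
                prize = baseline.prize(ind, phase)
            used_prizes.loc[ind, phase] = prize
            kept = [e for e in evs if e.intervened(phase, prize) >= 0.0]
            if kept:
                row[phase] = float(
                    np.mean([e.cost_savings(phase, prize, inefficiency) for e in kept])
                )
            else:
                row[phase] = float("nan")
            for e in kept:
                dist_rows.append(
                    {
                        "Indication": ind,
                        "prize_phase": phase,
                        "indirect_cost_per_approval": -e.indirect(phase, prize)
                        / e.p_reach_market,
                        "direct_cost_per_approval": -e.direct(inefficiency)
                        / e.p_reach_market,
                    }
                )
        rows.append(row)
    savings = pd.DataFrame(rows).set_index("Indication")
    return ScenarioResult(
        mean_savings=savings,
        distributions=pd.DataFrame(dist_rows),
        prizes=used_prizes,
        inefficiency=inefficiency,
        target_pgo=target_pgo,
        n_samples=n_samples,
        seed=seed,
    )
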