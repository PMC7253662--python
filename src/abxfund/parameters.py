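"""Input parameter tables for the antibiotic-development funding model.

The model prices hypothetical antibiotic projects against six clinical
indications.  Every stochastic input — per-phase development time, cost and
success probability, market size, launch success, generic entry, discount
rates — is described by a triangular (or degenerate/uniform) distribution
whose parameters ship with the package as plain CSV tables.  This module
parses those tables into validated domain objects and owns the run
configuration shared by all experiments.

Units are normalised on load: times to years, percentages to fractions,
money stays in million USD.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "INDICATIONS",
    "DEV_PHASES",
    "PRIZE_PHASES",
    "MARKET_LIFE_YEARS",
    "TriangularParam",
    "PhaseSpec",
    "MarketSpec",
    "AdditionalCostItem",
    "EconomyConfig",
    "IndicationSpec",
    "ParameterError",
    "load_parameters",
    "validate_config",
]

#: The six target indications, alphabetical (matching the input tables).
INDICATIONS = ("ABOM", "ABSSSI", "CABP", "CIAI", "CUTI", "HABP/VABP")

#: Development phases in chronological order.  "P4" covers everything
#: between the end of phase 3 and the first year of sales.
DEV_PHASES = ("PC", "P1", "P2", "P3", "P4")

#: Phases at which a lump-sum entry reward may be attached.  "M1" is market
#: entry; pre-clinical entry prizes are excluded because the valuation
#: viewpoint is pre-clinical and such a prize would escape discounting.
PRIZE_PHASES = ("P1", "P2", "P3", "P4", "M1")

#: Total product (market) life in years.
MARKET_LIFE_YEARS = 20


class ParameterError(ValueError):
    """Raised when an input table or configuration violates an invariant."""


@dataclass(frozen=True)
class TriangularParam:
    """Parameters (min, mode, max) of a triangular distribution.

    The degenerate form ``min == mode == max`` encodes a fixed constant.
    """

    min: float
    mode: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mode <= self.max):
            raise ParameterError(
                f"triangular requires min <= mode <= max, got "
                f"({self.min}, {self.mode}, {self.max})"
            )

    @classmethod
    def fixed(cls, value: float) -> "TriangularParam":
        return cls(value, value, value)

    @property
    def is_degenerate(self) -> bool:
        return self.min == self.max

    @property
    def mean(self) -> float:
        return (self.min + self.mode + self.max) / 3.0

    def scaled(self, factor: float) -> "TriangularParam":
        return TriangularParam(self.min * factor, self.mode * factor, self.max * factor)


@dataclass(frozen=True)
class PhaseSpec:
    """One development phase of one indication.

    ``time`` is in years, ``cost`` in million USD, ``prob_success`` a
    fraction in [0, 1].
    """

    phase_id: str
    time: TriangularParam
    cost: TriangularParam
    prob_success: TriangularParam

    def __post_init__(self) -> None:
        if self.phase_id not in DEV_PHASES:
            raise ParameterError(f"unknown phase_id {self.phase_id!r}")
        if self.time.min <= 0:
            raise ParameterError(f"{self.phase_id}: time.min must be > 0")
        if not (0.0 <= self.prob_success.min and self.prob_success.max <= 1.0):
            raise ParameterError(
                f"{self.phase_id}: prob_success bounds must lie in [0, 1], got "
                f"({self.prob_success.min}, {self.prob_success.max})"
            )


@dataclass(frozen=True)
class MarketSpec:
    """Market model for one indication.

    Annual revenue in market year ``y`` is market size times a share that
    interpolates between ``share_lower[y]`` and ``share_upper[y]``; the
    interpolation position is set once per project by the launch-success
    draw.  Revenues drop by a sampled fraction after generic entry.
    """

    market_size: TriangularParam  # million USD / year; sampled Uniform(min, max)
    share_lower: tuple[float, ...]  # 20 fractions
    share_upper: tuple[float, ...]
    launch_success: TriangularParam  # fraction
    generic_entry_year: TriangularParam  # years after market entry
    generic_revenue_reduction: TriangularParam  # fraction
    market_life_years: int = MARKET_LIFE_YEARS
    # True when the upper bound was not printed for this indication but
    # inherited from the size table's single shared maximum
    market_size_max_inherited: bool = False

    def __post_init__(self) -> None:
        if self.market_life_years != MARKET_LIFE_YEARS:
            raise ParameterError("market_life_years must equal 20")
        if len(self.share_lower) != MARKET_LIFE_YEARS or len(self.share_upper) != MARKET_LIFE_YEARS:
            raise ParameterError("share vectors must have 20 entries")
        for y, (lo, hi) in enumerate(zip(self.share_lower, self.share_upper), start=1):
            if lo > hi:
                raise ParameterError(f"share_lower > share_upper in market year {y}")
        for y in range(1, 10):
            if self.share_lower[y] < self.share_lower[y - 1] or self.share_upper[y] < self.share_upper[y - 1]:
                raise ParameterError("market share envelopes must be non-decreasing through year 10")
        for y in range(10, MARKET_LIFE_YEARS):
            if self.share_lower[y] != self.share_lower[9] or self.share_upper[y] != self.share_upper[9]:
                raise ParameterError("market share envelopes must be constant in years 10-20")


@dataclass(frozen=True)
class AdditionalCostItem:
    """A supply-chain / non-clinical / post-approval cost line item.

    ``allocation`` maps phase ids (development phases or market years
    M1..M3) to weights summing to 1; the item's sampled cost is split
    across phases by these weights.
    """

    label: str
    cost: TriangularParam  # million USD
    allocation: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.allocation.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"{self.label}: allocation weights sum to {total}, expected 1"
            )
        valid = set(DEV_PHASES) | {f"M{y}" for y in range(1, MARKET_LIFE_YEARS + 1)}
        for key in self.allocation:
            if key not in valid:
                raise ParameterError(f"{self.label}: unknown allocation target {key!r}")


@dataclass(frozen=True)
class IndicationSpec:
    """All inputs for one indication: phases, market, extra cost items."""

    indication: str
    phases: tuple[PhaseSpec, ...]
    market: MarketSpec
    extra_costs: tuple[AdditionalCostItem, ...]

    def phase(self, phase_id: str) -> PhaseSpec:
        for p in self.phases:
            if p.phase_id == phase_id:
                return p
        raise KeyError(phase_id)


@dataclass
class EconomyConfig:
    """Run configuration: discount rates, inefficiency, prize placement.

    The private discount rate is the developer's opportunity cost of
    capital; the social rate is the public benefactor's, drawn uniformly
    between ``social_discount_low`` and ``social_discount_high``.
    ``inefficiency`` inflates direct-funding costs by (1 + i).
    """

    private_discount: TriangularParam = field(
        default_factory=lambda: TriangularParam(0.09, 0.11, 0.24)
    )
    social_discount_low: float = 0.035
    social_discount_high: float = 0.045
    inefficiency: float = 0.0
    prize_phase: str = "none"  # one of PRIZE_PHASES or "none"
    prize_size: float = 0.0  # million USD
    seed: int = 0
    n_samples: int = 2000

    def __post_init__(self) -> None:
        validate_config(self)


def validate_config(cfg: EconomyConfig) -> EconomyConfig:
    """Validate and return a run configuration.

    Raises :class:`ParameterError` naming the offending field.
    """
    if cfg.prize_size < 0:
        raise ParameterError(f"prize_size must be >= 0, got {cfg.prize_size}")
    if not (0.0 <= cfg.inefficiency <= 1.0):
        raise ParameterError(
            f"inefficiency must lie in [0, 1], got {cfg.inefficiency}"
        )
    if cfg.prize_phase not in PRIZE_PHASES + ("none",):
        raise ParameterError(f"prize_phase must be one of {PRIZE_PHASES} or 'none'")
    if not (0 < cfg.social_discount_low <= cfg.social_discount_high):
        raise ParameterError("social discount bounds must satisfy 0 < low <= high")
    if cfg.n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    return cfg


# ---------------------------------------------------------------------------
# Fixture loading

_DATA_FILES = (
    "phase_parameters.csv",
    "market_size.csv",
    "market_share.csv",
    "additional_parameters.csv",
    "additional_costs.csv",
)


def _data_dir() -> Path:
    return Path(str(resources.files("abxfund").joinpath("data")))


_SPREAD_RE = re.compile(r"^\s*(PC|P[1-4]|M\d+)\s*(?:\((\d+(?:\.\d+)?)%\))?\s*$")


def _parse_allocation(spread: str) -> dict[str, float]:
    """Parse an allocation such as ``"P3 (75%), P4 (25%)"`` or ``"P1, P2"``.

    Targets without an explicit percentage share the remaining weight
    equally.
    """
    parts = [p for p in spread.split(",") if p.strip()]
    explicit: dict[str, float] = {}
    implicit: list[str] = []
    for part in parts:
        m = _SPREAD_RE.match(part)
        if m is None:
            raise ParameterError(f"cannot parse allocation element {part!r}")
        phase, pct = m.group(1), m.group(2)
        if pct is None:
            implicit.append(phase)
        else:
            explicit[phase] = float(pct) / 100.0
    remaining = 1.0 - sum(explicit.values())
    alloc = dict(explicit)
    for phase in implicit:
        alloc[phase] = remaining / len(implicit)
    return alloc


def _tri_row(row: pd.Series, prefix: str, scale: float = 1.0) -> TriangularParam:
    return TriangularParam(
        float(row[f"{prefix} min"]) * scale,
        float(row[f"{prefix} mid"]) * scale,
        float(row[f"{prefix} max"]) * scale,
    )


def load_parameters(source: str | Path | None = None) -> dict[str, IndicationSpec]:
    """Load the packaged parameter tables (or a user directory of the same
    layout) into one :class:`IndicationSpec` per indication.

    Times are converted from months to years, probabilities and percentages
    to fractions.  Money stays in million USD.
    """
    base = Path(source) if source is not None else _data_dir()
    for name in _DATA_FILES:
        if not (base / name).exists():
            raise ParameterError(f"missing parameter table {name} in {base}")

    phases_df = pd.read_csv(base / "phase_parameters.csv")
    size_df = pd.read_csv(base / "market_size.csv")
    if size_df["Max"].notna().sum() == 0:
        raise ParameterError("market size table must print at least one Max")
    global_size_max = float(size_df["Max"].max())
    share_df = pd.read_csv(base / "market_share.csv", dtype={"Years": str})
    extra_df = pd.read_csv(base / "additional_parameters.csv", index_col="Parameter")
    costs_df = pd.read_csv(base / "additional_costs.csv")

    # --- market share envelopes: expand the "10:20" row to years 10..20
    lower = [float("nan")] * MARKET_LIFE_YEARS
    upper = [float("nan")] * MARKET_LIFE_YEARS
    for _, row in share_df.iterrows():
        years = str(row["Years"])
        lo, hi = float(row["Min"]) / 100.0, float(row["Max"]) / 100.0
        if ":" in years:
            start, stop = (int(x) for x in years.split(":"))
        else:
            start = stop = int(years)
        for y in range(start, stop + 1):
            lower[y - 1] = lo
            upper[y - 1] = hi
    if any(pd.isna(lower)) or any(pd.isna(upper)):
        raise ParameterError("market share table does not cover years 1-20")

    def extra_param(name: str, scale: float) -> TriangularParam:
        row = extra_df.loc[name]
        return TriangularParam(
            float(row["Min"]) * scale, float(row["Mid"]) * scale, float(row["Max"]) * scale
        )

    launch = extra_param("Launch success probability (%)", 0.01)
    generic_red = extra_param("Generic entry revenue reduction (%)", 0.01)
    generic_year = extra_param("Generic entry (years)", 1.0)
    if "Private discount rate (%)" not in extra_df.index:
        raise ParameterError("missing 'Private discount rate (%)' row")

    items: list[AdditionalCostItem] = []
    for _, row in costs_df.iterrows():
        items.append(
            AdditionalCostItem(
                label=str(row["Activity"]),
                cost=TriangularParam(float(row["Min"]), float(row["Mid"]), float(row["Max"])),
                allocation=_parse_allocation(str(row["Spread across"])),
            )
        )

    specs: dict[str, IndicationSpec] = {}
    for ind in INDICATIONS:
        sub = phases_df[phases_df["Indication"] == ind]
        if len(sub) != len(DEV_PHASES):
            raise ParameterError(f"{ind}: expected {len(DEV_PHASES)} phase rows, got {len(sub)}")
        phase_specs = []
        for phase_id in DEV_PHASES:
            row = sub[sub["Phase"] == phase_id]
            if len(row) != 1:
                raise ParameterError(f"{ind}: phase {phase_id} missing or duplicated")
            row = row.iloc[0]
            if pd.isna(row["Cost min"]) and pd.isna(row["Cost max"]):
                # only a most-likely value printed: treat as a fixed constant
                cost = TriangularParam.fixed(float(row["Cost mid"]))
            else:
                cost = _tri_row(row, "Cost")
            phase_specs.append(
                PhaseSpec(
                    phase_id=phase_id,
                    time=_tri_row(row, "Time", scale=1.0 / 12.0),  # months -> years
                    cost=cost,
                    prob_success=_tri_row(row, "Prob", scale=0.01),
                )
            )

        srow = size_df[size_df["Indication"] == ind]
        if len(srow) != 1:
            raise ParameterError(f"{ind}: market size row missing or duplicated")
        srow = srow.iloc[0]
        lo = float(srow["Min"])
        # The size table prints a lower bound per indication but a single
        # upper bound for the whole column; annual market size is sampled
        # uniformly between the indication's bound and that shared maximum.
        # (No mode is printed, so a triangular would be unjustified.)
        hi = global_size_max
        max_inherited = pd.isna(srow["Max"])
        if hi < lo:
            raise ParameterError(f"{ind}: market size min {lo} exceeds max {hi}")
        size = TriangularParam(lo, (lo + hi) / 2.0, hi)

        market = MarketSpec(
            market_size=size,
            share_lower=tuple(lower),
            share_upper=tuple(upper),
            launch_success=launch,
            generic_entry_year=generic_year,
            generic_revenue_reduction=generic_red,
            market_size_max_inherited=max_inherited,
        )
        specs[ind] = IndicationSpec(
            indication=ind,
            phases=tuple(phase_specs),
            market=market,
            extra_costs=tuple(items),
        )
    return specs


def dump_parameters(
    specs: Mapping[str, IndicationSpec],
    out_dir: str | Path,
    private_discount: TriangularParam = TriangularParam(0.09, 0.11, 0.24),
) -> None:
    """Serialize specs back to the CSV table layout.

    ``load_parameters(out_dir)`` on the result reproduces the input specs
    exactly (round-trip contract).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    rows = []
    for ind in INDICATIONS:
        for p in specs[ind].phases:
            cost = p.cost
            degenerate_cost = cost.is_degenerate
            rows.append(
                {
                    "Phase": p.phase_id,
                    "Indication": ind,
                    "Time min": fmt(p.time.min * 12),
                    "Time mid": fmt(p.time.mode * 12),
                    "Time max": fmt(p.time.max * 12),
                    "Cost min": "" if degenerate_cost else fmt(cost.min),
                    "Cost mid": fmt(cost.mode),
                    "Cost max": "" if degenerate_cost else fmt(cost.max),
                    "Prob min": fmt(p.prob_success.min * 100),
                    "Prob mid": fmt(p.prob_success.mode * 100),
                    "Prob max": fmt(p.prob_success.max * 100),
                }
            )
    pd.DataFrame(rows).to_csv(out / "phase_parameters.csv", index=False)

    size_rows = []
    for ind in INDICATIONS:
        m = specs[ind].market
        size_rows.append(
            {
                "Indication": ind,
                "Min": fmt(m.market_size.min),
                "Max": "" if m.market_size_max_inherited else fmt(m.market_size.max),
            }
        )
    pd.DataFrame(size_rows).to_csv(out / "market_size.csv", index=False)

    m = specs[INDICATIONS[0]].market  # share envelopes are shared
    share_rows = [
        {"Years": str(y + 1), "Min": fmt(m.share_lower[y] * 100), "Max": fmt(m.share_upper[y] * 100)}
        for y in range(9)
    ]
    share_rows.append(
        {"Years": "10:20", "Min": fmt(m.share_lower[9] * 100), "Max": fmt(m.share_upper[9] * 100)}
    )
    pd.DataFrame(share_rows).to_csv(out / "market_share.csv", index=False)

    extra_rows = [
        {
            "Parameter": "Launch success probability (%)",
            "Min": fmt(m.launch_success.min * 100),
            "Mid": fmt(m.launch_success.mode * 100),
            "Max": fmt(m.launch_success.max * 100),
        },
        {
            "Parameter": "Generic entry revenue reduction (%)",
            "Min": fmt(m.generic_revenue_reduction.min * 100),
            "Mid": fmt(m.generic_revenue_reduction.mode * 100),
            "Max": fmt(m.generic_revenue_reduction.max * 100),
        },
        {
            "Parameter": "Generic entry (years)",
            "Min": fmt(m.generic_entry_year.min),
            "Mid": fmt(m.generic_entry_year.mode),
            "Max": fmt(m.generic_entry_year.max),
        },
        {
            "Parameter": "Private discount rate (%)",
            "Min": fmt(private_discount.min * 100),
            "Mid": fmt(private_discount.mode * 100),
            "Max": fmt(private_discount.max * 100),
        },
    ]
    pd.DataFrame(extra_rows).to_csv(out / "additional_parameters.csv", index=False)

    cost_rows = []
    for item in specs[INDICATIONS[0]].extra_costs:
        n = len(item.allocation)
        equal = all(abs(w - 1.0 / n) < 1e-9 for w in item.allocation.values())
        if equal:
            spread = ", ".join(item.allocation)
        else:
            spread = ", ".join(f"{k} ({w * 100:g}%)" for k, w in item.allocation.items())
        cost_rows.append(
            {
                "Activity": item.label,
                "Min": fmt(item.cost.min),
                "Mid": fmt(item.cost.mode),
                "Max": fmt(item.cost.max),
                "Spread across": spread,
            }
        )
    pd.DataFrame(cost_rows).to_csv(out / "additional_costs.csv", index=False)


def load_reference_prizes(source: str | Path | None = None) -> pd.DataFrame:
    """Reference schedule of entry-reward sizes (million USD) calibrated to
    a 90% conditional go-probability for these parameter tables.

    Rows are indications, columns prize phases P1..M1.  The scenario
    experiment accepts this schedule as its prize input; re-solving the
    schedule from a fresh fit reproduces it only up to the considerable
    Monte Carlo noise of the logistic inversion.
    """
    base = Path(source) if source is not None else _data_dir()
    df = pd.read_csv(base / "reference_prizes_p90.csv", index_col="Indication")
    if list(df.index) != list(INDICATIONS):
        raise ParameterError("reference prize schedule must cover the six indications")
    if list(df.columns) != list(PRIZE_PHASES):
        raise ParameterError(f"reference prize schedule columns must be {PRIZE_PHASES}")
    return df.astype(float)


def load_private_discount(source: str | Path | None = None) -> TriangularParam:
    """Read the private discount-rate triangular from a parameter directory."""
    base = Path(source) if source is not None else _data_dir()
    df = pd.read_csv(base / "additional_parameters.csv", index_col="Parameter")
    row = df.loc["Private discount rate (%)"]
    return TriangularParam(
        float(row["Min"]) / 100, float(row["Mid"]) / 100, float(row["Max"]) / 100
    )


def config_as_dict(cfg: EconomyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["private_discount"] = dataclasses.asdict(cfg.private_discount)
    return d
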