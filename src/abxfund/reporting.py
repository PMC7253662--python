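"""Serialization of experiment results to CSV tables plus a run manifest.

Output tables mirror the conventional presentation — probabilities as
percentages, money in million USD, Min/Max summary rows on the prize and
savings tables — while all internal computation stays in fractions and
million USD.  Every write goes through one serializer so that reading a
written table back reproduces the in-memory values exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .experiments import (
    BaselineResult,
    FrontierFit,
    GridCell,
    ScenarioResult,
    grid_to_frame,
)
from .parameters import config_as_dict, EconomyConfig, _data_dir, _DATA_FILES

__all__ = [
    "RunManifest",
    "write_table",
    "read_table",
    "write_baseline_tables",
    "write_grid_tables",
    "write_scenario_tables",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"  # full float round-trip at readable width


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    command: str
    seed: int
    config: dict
    fixture_checksum: str
    package_version: str
    python_version: str
    timestamp: str


def fixture_checksum(source: str | Path | None = None) -> str:
    base = Path(source) if source is not None else _data_dir()
    h = hashlib.sha256()
    for name in _DATA_FILES:
        h.update((base / name).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int,
    cfg: EconomyConfig | None = None,
    params_dir: str | Path | None = None,
    extra: Mapping[str, object] | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        seed=seed,
        config=config_as_dict(cfg) if cfg is not None else {},
        fixture_checksum=fixture_checksum(params_dir),
        package_version=_pkg_version,
        python_version=platform.python_version(),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    d = dataclasses.asdict(manifest)
    if extra:
        d.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """The single CSV serializer used for every result table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)
    return path


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def _with_min_max(df: pd.DataFrame) -> pd.DataFrame:
    """Append Min/Max summary rows over the indication rows."""
    out = df.copy()
    out.loc["Min"] = df.min()
    out.loc["Max"] = df.max()
    return out


def write_baseline_tables(res: BaselineResult, out_dir: str | Path) -> list[Path]:
    """Write baseline decision ratios (percent), response-model fits, and
    the solved prize schedule."""
    out = Path(out_dir)
    paths = []
    go = (res.go_ratios[["Go", "No"]] * 100.0).copy()
    go["n"] = res.go_ratios["n"]
    go = go.sort_values("Go", ascending=False)
    paths.append(write_table(go, out / "baseline_decisions.csv"))

    paths.append(
        write_table(_with_min_max(res.prizes), out / "solved_prizes.csv")
    )

    fit_rows = []
    for fits in (res.improvement_fits, res.pgo_fits):
        for (ind, phase), f in fits.items():
            fit_rows.append(dataclasses.asdict(f))
    paths.append(
        write_table(pd.DataFrame(fit_rows), out / "response_fits.csv", index=False)
    )
    return paths


def write_grid_tables(
    cells: Sequence[GridCell],
    frontier: Mapping[tuple[str, str], FrontierFit] | None,
    out_dir: str | Path,
) -> list[Path]:
    out = Path(out_dir)
    paths = [write_table(grid_to_frame(cells), out / "grid.csv", index=False)]
    if frontier is not None:
        rows = []
        for f in frontier.values():
            d = dataclasses.asdict(f)
            d.pop("points")
            rows.append(d)
        paths.append(
            write_table(pd.DataFrame(rows), out / "frontier.csv", index=False)
        )
    return paths


def write_scenario_tables(res: ScenarioResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    paths = [
        write_table(_with_min_max(res.mean_savings), out / "scenario_savings.csv"),
        write_table(res.prizes, out / "scenario_prizes.csv"),
        write_table(res.distributions, out / "cost_distributions.csv", index=False),
    ]
    return paths
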