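"""Report rendering and run manifests.

CSV is the canonical tabular output; markdown rendering is presentational.
The estimand-comparison report mirrors the attribute-table layout: one
column per named strategy configuration, rows for population, endpoint,
treatment condition, summary measure, and the per-ICE strategies, followed
by the computed per-dose utilities, MTD and OBD.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .estimand import StrategyConfig

__all__ = ["RunManifest", "render_reports", "estimand_attribute_table"]

PathLike = Union[str, Path]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to replay a run exactly."""

    config_digest: str
    seed: int
    command: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    software_version: str = _VERSION
    python_version: str = field(default_factory=platform.python_version)

    @classmethod
    def create(cls, config_text: str, seed: int, command: str) -> "RunManifest":
        digest = hashlib.sha256(config_text.encode()).hexdigest()
        return cls(config_digest=digest, seed=seed, command=command)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def write(self, path: PathLike) -> None:
        Path(path).write_text(self.to_json() + "\n")


def estimand_attribute_table(
    comparison: pd.DataFrame, configs: Mapping[str, StrategyConfig]
) -> pd.DataFrame:
    """Attribute-style rendering of an estimand comparison.

    Fixed rows (population, endpoint, treatment condition, summary measure),
    one row per ICE type showing the configured strategy, then the computed
    per-dose utilities, admissible set, MTD and OBD — one column per estimand.
    """
    columns = list(comparison.index)
    rows: dict[str, list[object]] = {
        "population": ["as defined by trial inclusion/exclusion criteria"] * len(columns),
        "endpoint": ["binary efficacy and toxicity (DLT) combined into outcome category"]
        * len(columns),
        "treatment_condition": ["investigational compound from first dose"] * len(columns),
        "population_level_summary": ["posterior expected utility per dose"] * len(columns),
    }
    ice_types = sorted({t for cfg in configs.values() for t in cfg.per_ice_strategy})
    for t in ice_types:
        rows[f"ice:{t}"] = [configs[name].per_ice_strategy.get(t, "") for name in columns]
    for col in comparison.columns:
        rows[col] = [comparison.loc[name, col] for name in columns]
    return pd.DataFrame(rows, index=columns).T


def _to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style table rendering (index as first column)."""
    header = [df.index.name or ""] + [str(c) for c in df.columns]
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [str(v) for v in row.tolist()]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_reports(
    results: Mapping[str, pd.DataFrame],
    out_dir: PathLike,
    format: str = "csv",
) -> list[Path]:
    """Write each named result table deterministically; returns paths written."""
    if format not in ("csv", "markdown"):
        raise ValueError("format must be 'csv' or 'markdown'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        if format == "csv":
            path = out / f"{name}.csv"
            df.to_csv(path)
        else:
            path = out / f"{name}.md"
            path.write_text(_to_markdown(df) + "\n")
        written.append(path)
    return written
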