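"""Readers and writers for breakdown tables, counts and run manifests.

Tables are UTF-8 comma-delimited CSV with the layout of the percentage
tables: one row per mechanism, columns size 1..report_size followed by a
``>report_size`` overflow column, percentages rounded to two decimals at
serialisation only.  Manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .distributions import MECHANISM_ROWS, AggregateDistribution, BreakdownTable


def write_breakdown(table: BreakdownTable, path: str | Path, decimals: int = 2) -> None:
    """Write a percentage table to CSV (2-decimal entries)."""
    if table.total_entities() <= 0:
        raise ValueError("refusing to write an empty table")
    frame = table.to_frame().round(decimals)
    frame.index.name = "mechanism"
    frame.to_csv(path, float_format=f"%.{decimals}f")


def read_breakdown(path: str | Path) -> BreakdownTable:
    """Read a breakdown CSV written by :func:`write_breakdown`."""
    frame = pd.read_csv(path, index_col="mechanism")
    if list(frame.index) != list(MECHANISM_ROWS):
        raise ValueError(f"{path}: malformed table, expected rows {MECHANISM_ROWS}")
    last = frame.columns[-1]
    if not last.startswith(">"):
        raise ValueError(f"{path}: missing overflow column")
    report_size = int(last[1:])
    expected = [str(n) for n in range(1, report_size + 1)] + [last]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: malformed size columns")
    return BreakdownTable("cell", frame.to_numpy(dtype=float), report_size)


def write_counts(dist: AggregateDistribution, path: str | Path) -> None:
    """Write raw entity counts (full precision) to CSV."""
    frame = dist.to_frame()
    frame.index.name = "mechanism"
    frame.to_csv(path)


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    config: dict[str, Any]
    params: dict[str, Any]
    scenarios: list[str]
    t_end_minutes: float
    snapshot_times: list[float]
    solver: dict[str, Any]
    software_version: str
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)
    failed_scenarios: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_json(data: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")
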