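"""CSV input/output and run manifests.

The canonical on-disk format is a tidy trial table, one trial per row, with
columns ``cell_id, paradigm, condition, direction, trial_index, rate``.
Because published spike-count tables come with arbitrary headers, a
:class:`ColumnMap` adapts a source CSV to the canonical fields; spike counts
plus a window length are converted to rates on the fly.

Result tables are written as long-format CSV with a JSON run manifest
(configuration, seed, package version) alongside, so a rerun can reproduce
outputs byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import CONDITIONS, GRID, PARADIGMS, TuningDataset

__all__ = ["ColumnMap", "ValidationError", "read_trials", "write_trials", "write_tables"]

CANONICAL = ("cell_id", "paradigm", "condition", "direction", "trial_index", "rate")


class ValidationError(ValueError):
    """Carries a row-level error report: list of (file, line, reason)."""

    def __init__(self, report: list[tuple[str, int, str]]):
        self.report = report
        preview = "; ".join(f"{f}:{ln}: {r}" for f, ln, r in report[:5])
        more = "" if len(report) <= 5 else f" (+{len(report) - 5} more)"
        super().__init__(f"{len(report)} invalid row(s): {preview}{more}")


@dataclass
class ColumnMap:
    """Mapping from canonical fields to source CSV column names.

    Either ``rate`` or both ``spike_count`` and ``window_seconds`` must be
    mapped; in the latter case rate = count / window.
    """

    cell_id: str = "cell_id"
    paradigm: str = "paradigm"
    condition: str = "condition"
    direction: str = "direction"
    trial_index: str = "trial_index"
    rate: str | None = "rate"
    spike_count: str | None = None
    window_seconds: float | str | None = None

    def __post_init__(self) -> None:
        if self.rate is None and (self.spike_count is None or self.window_seconds is None):
            raise ValueError("map either 'rate' or 'spike_count' + 'window_seconds'")


def read_trials(path, column_map: ColumnMap | None = None) -> TuningDataset:
    """Read a trial table CSV into a validated :class:`TuningDataset`."""
    column_map = column_map or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path)
    needed = [column_map.cell_id, column_map.paradigm, column_map.condition,
              column_map.direction, column_map.trial_index]
    if column_map.rate is not None:
        needed.append(column_map.rate)
    else:
        needed.append(column_map.spike_count)
        if isinstance(column_map.window_seconds, str):
            needed.append(column_map.window_seconds)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError([(str(path), 0, f"missing column {c!r}") for c in missing])

    out = pd.DataFrame({
        "cell_id": df[column_map.cell_id].astype(str),
        "paradigm": df[column_map.paradigm].astype(str),
        "condition": df[column_map.condition].astype(str),
        "direction": pd.to_numeric(df[column_map.direction], errors="coerce"),
        "trial_index": pd.to_numeric(df[column_map.trial_index], errors="coerce"),
    })
    if column_map.rate is not None:
        out["rate"] = pd.to_numeric(df[column_map.rate], errors="coerce")
    else:
        counts = pd.to_numeric(df[column_map.spike_count], errors="coerce")
        if isinstance(column_map.window_seconds, str):
            window = pd.to_numeric(df[column_map.window_seconds], errors="coerce")
        else:
            window = float(column_map.window_seconds)
        out["rate"] = counts / window

    report: list[tuple[str, int, str]] = []
    for i, row in out.iterrows():
        line = i + 2  # header + 1-based
        if pd.isna(row["rate"]):
            report.append((str(path), line, "non-numeric rate"))
        elif row["rate"] < 0:
            report.append((str(path), line, f"negative rate {row['rate']}"))
        if pd.isna(row["direction"]) or row["direction"] not in GRID:
            report.append((str(path), line, f"direction {row['direction']} off the 30-degree grid"))
        if row["paradigm"] not in PARADIGMS:
            report.append((str(path), line, f"unknown paradigm {row['paradigm']!r}"))
        if row["condition"] not in CONDITIONS:
            report.append((str(path), line, f"unknown condition {row['condition']!r}"))
    if report:
        raise ValidationError(report)
    return TuningDataset(records=out.reset_index(drop=True))


def write_trials(dataset: TuningDataset, path) -> Path:
    path = Path(path)
    dataset.records.loc[:, list(CANONICAL)].to_csv(path, index=False)
    return path


def write_tables(results: pd.DataFrame, path, manifest: dict | None = None) -> Path:
    """Write a long-format result CSV plus a JSON run manifest next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)
    from . import __version__

    meta = {
        "tunefree_version": __version__,
        "python": platform.python_version(),
        "rows": int(len(results)),
        "columns": list(results.columns),
    }
    meta.update(manifest or {})
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path
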