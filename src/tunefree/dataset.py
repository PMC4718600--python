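"""Canonical representation of tuning experiments.

A :class:`TuningDataset` holds trial-level firing rates (one row per trial)
for a population of cells recorded under one of two paradigms
(``spatially_separate`` or ``transparent``) and up to five conditions
(``uni``, ``uni1``, ``uni2`` single-stimulus; ``afix``, ``ain`` composite).
Stimulus direction lives on the fixed 12-point grid 0, 30, ..., 330 degrees.

Downstream analyses assume the conventional alignment in which the maximum
trial-mean firing rate of the single-stimulus (uni) condition sits at the
angular coordinate 240 degrees; for cells lacking a uni condition the right
peak of the afix condition is aligned to 240 instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GRID",
    "K",
    "PARADIGMS",
    "CONDITIONS",
    "UNI_CONDITIONS",
    "BIMODAL_CONDITIONS",
    "ALIGN_TARGET",
    "InclusionError",
    "AlignmentError",
    "TuningCurve",
    "TuningDataset",
    "modality_of",
    "select_uni",
    "build_curves",
    "align",
]

K = 12
GRID = np.arange(0, 360, 30, dtype=float)
PARADIGMS = ("spatially_separate", "transparent")
CONDITIONS = ("uni", "uni1", "uni2", "afix", "ain")
UNI_CONDITIONS = ("uni", "uni1", "uni2")
BIMODAL_CONDITIONS = ("afix", "ain")
ALIGN_TARGET = 240.0

REQUIRED_COLUMNS = ("cell_id", "paradigm", "condition", "direction", "trial_index", "rate")


class InclusionError(ValueError):
    """A (cell, condition, direction) violates the >= 2 trials inclusion rule."""


class AlignmentError(ValueError):
    """A cell lacks both a uni-type and an afix condition."""


def modality_of(condition: str) -> str:
    return "bimodal" if condition in BIMODAL_CONDITIONS else "unimodal"


@dataclass
class TuningCurve:
    """Trial-averaged tuning curve of one cell in one condition.

    ``y`` is the per-direction trial mean (s^-1), ``sigma`` the per-direction
    trial standard deviation (ddof=1), ``n_trials`` the trial count, all on
    the 12-point ``grid``.
    """

    cell_id: str
    paradigm: str
    condition: str
    grid: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        for name in ("grid", "y", "sigma", "n_trials"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.grid) == len(self.y) == len(self.sigma) == len(self.n_trials) == K):
            raise ValueError(f"TuningCurve arrays must all have length {K}")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @property
    def modality(self) -> str:
        return modality_of(self.condition)


@dataclass
class TuningDataset:
    """Trial-level records plus the per-cell alignment offsets (degrees)."""

    records: pd.DataFrame
    alignment_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean)."""
        problems: list[str] = []
        df = self.records
        bad_dir = ~df["direction"].isin(GRID)
        if bad_dir.any():
            problems.append(
                f"{int(bad_dir.sum())} record(s) with direction off the 30-degree grid"
            )
        if (df["rate"] < 0).any():
            problems.append("negative firing rates present")
        counts = df.groupby(["cell_id", "paradigm", "condition", "direction"]).size()
        thin = counts[counts < 2]
        for key in thin.index:
            problems.append(f"fewer than 2 trials at {key}")
        for cell, off in self.alignment_offsets.items():
            if off % 30 != 0:
                problems.append(f"alignment offset for cell {cell} not a multiple of 30")
        return problems

    def cells(self) -> list:
        return sorted(self.records["cell_id"].unique())

    def conditions_of(self, cell_id) -> list[str]:
        present = self.records.loc[self.records["cell_id"] == cell_id, "condition"].unique()
        return [c for c in CONDITIONS if c in present]


def select_uni(dataset: TuningDataset, cell_id) -> str | None:
    """Pick the single-stimulus condition to analyze for a cell.

    ``uni2`` is preferred when both uni1/uni2 were recorded (spatially
    separate paradigm); otherwise the single ``uni``/``uni1`` present.
    Returns ``None`` for cells without any uni-type condition (these are
    retained in the dataset but excluded from uni-dependent analyses).
    """
    present = dataset.conditions_of(cell_id)
    for name in ("uni2", "uni", "uni1"):
        if name in present:
            return name
    return None


def build_curves(dataset: TuningDataset) -> list[TuningCurve]:
    """One trial-averaged :class:`TuningCurve` per (cell, paradigm, condition).

    Raises :class:`InclusionError` naming the first offender if any recorded
    (cell, condition, direction) carries fewer than two trials.
    """
    curves: list[TuningCurve] = []
    for (cell, paradigm, cond), grp in dataset.records.groupby(
        ["cell_id", "paradigm", "condition"], sort=True
    ):
        agg = grp.groupby("direction")["rate"].agg(["mean", "std", "count"])
        agg = agg.reindex(GRID)
        if agg["count"].isna().any() or (agg["count"] < 2).any():
            bad = agg.index[agg["count"].isna() | (agg["count"] < 2)][0]
            raise InclusionError(
                f"cell {cell!r} condition {cond!r} has < 2 trials at direction {bad:g}"
            )
        curves.append(
            TuningCurve(
                cell_id=cell,
                paradigm=paradigm,
                condition=cond,
                grid=GRID.copy(),
                y=agg["mean"].to_numpy(),
                sigma=agg["std"].to_numpy(),
                n_trials=agg["count"].to_numpy(),
            )
        )
    return curves


def _trial_mean_by_direction(df: pd.DataFrame) -> pd.Series:
    return df.groupby("direction")["rate"].mean().reindex(GRID)


def _argmax_angle(mean_by_dir: pd.Series) -> float:
    """Direction of the maximum trial-mean rate; ties -> smallest angle."""
    vals = mean_by_dir.to_numpy(dtype=float)
    return float(GRID[int(np.nanargmax(vals))])


def _afix_right_peak(mean_by_dir: pd.Series) -> float:
    """Right-peak direction of an unaligned afix curve.

    The composite stimulus places the two peaks 120 degrees apart.  The
    global maximum is one peak; its companion is whichever of +/-120 degrees
    responds more strongly.  Within the pair, the peak whose companion lies
    120 degrees counter-clockwise is the right peak (reconstruction of the
    original convention; deterministic).
    """
    vals = mean_by_dir.to_numpy(dtype=float)
    i_max = int(np.nanargmax(vals))
    i_plus = (i_max + 4) % K   # +120 degrees
    i_minus = (i_max - 4) % K  # -120 degrees
    if vals[i_plus] >= vals[i_minus]:
        # companion counter-clockwise: the maximum is the left peak
        return float(GRID[i_plus])
    return float(GRID[i_max])


def align(dataset: TuningDataset) -> TuningDataset:
    """Circularly relabel directions so each cell's reference peak sits at 240.

    The reference is the trial-mean maximum of the cell's uni condition
    (uni2 preferred), or the right peak of afix for cells without a uni
    condition.  The same multiple-of-30 offset is applied to every condition
    of the cell, and recorded in ``alignment_offsets``.  Idempotent.
    """
    df = dataset.records.copy()
    offsets: dict = {}
    for cell in dataset.cells():
        sub = df[df["cell_id"] == cell]
        uni = select_uni(dataset, cell)
        if uni is not None:
            ref = _argmax_angle(_trial_mean_by_direction(sub[sub["condition"] == uni]))
        elif "afix" in sub["condition"].unique():
            ref = _afix_right_peak(_trial_mean_by_direction(sub[sub["condition"] == "afix"]))
        else:
            raise AlignmentError(f"cell {cell!r} has neither a uni-type nor an afix condition")
        offset = (ALIGN_TARGET - ref) % 360.0
        offsets[cell] = offset
        df.loc[df["cell_id"] == cell, "direction"] = (
            sub["direction"] + offset
        ) % 360.0
    prior = dataset.alignment_offsets
    combined = {
        cell: (prior.get(cell, 0.0) + offsets[cell]) % 360.0 for cell in offsets
    }
    return TuningDataset(records=df, alignment_offsets=combined)
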