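import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tunefree.dataset import GRID, TuningCurve, TuningDataset

sys.path.insert(0, str(Path(__file__).parent))


def make_curve(y, sigma=None, cell_id="c0", paradigm="spatially_separate",
               condition="uni2", n_trials=5):
    y = np.asarray(y, dtype=float)
    sigma = np.ones_like(y) if sigma is None else np.asarray(sigma, dtype=float)
    return TuningCurve(cell_id=cell_id, paradigm=paradigm, condition=condition,
                       grid=GRID.copy(), y=y, sigma=sigma,
                       n_trials=np.full(len(y), n_trials))


def make_dataset(cell_rates: dict, paradigm="spatially_separate") -> TuningDataset:
    """cell_rates: {cell_id: {condition: {direction: [trial rates]}}}"""
    rows = []
    for cell, conds in cell_rates.items():
        for cond, by_dir in conds.items():
            for direction, rates in by_dir.items():
                for t, r in enumerate(rates):
                    rows.append({"cell_id": cell, "paradigm": paradigm,
                                 "condition": cond, "direction": float(direction),
                                 "trial_index": t, "rate": float(r)})
    return TuningDataset(records=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def example_curve_values():
    # the worked 12-point example used across feature tests
    return np.array([5, 6, 9, 15, 22, 14, 8, 4, 10, 21, 28, 12], dtype=float)
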