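"""Shared fixtures: small analytic ensembles and a mid-sized preset run.

The conjunctive toy (two independent units, both needed to win) is fully
enumerated with product weights, so every measure has a closed-form value
against which implementations are checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from causalworlds import ElectoralMap, WorldEnsemble, presets, score_all
from causalworlds.synthetic_data import forecast_2020_spec, simulate_forecast


def enumerate_product_ensemble(
    emap: ElectoralMap, probs: np.ndarray
) -> WorldEnsemble:
    """All 2^n worlds of mutually independent units with product weights."""
    n = emap.n_units
    grid = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)
    w = np.prod(np.where(grid == 1, probs, 1.0 - probs), axis=1)
    return WorldEnsemble(emap, grid, w)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Independent closed-form oracle: weighted population Pearson r."""
    x, y, w = map(np.asarray, (x, y, w))
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    return cov / np.sqrt((w @ (x - mx) ** 2) * (w @ (y - my) ** 2))


@pytest.fixture(scope="session")
def conjunctive_toy() -> WorldEnsemble:
    """A (p=.9, 2 votes) and B (p=.5, 1 vote); threshold 3: both needed."""
    emap = ElectoralMap(("A", "B"), (2, 1), 3)
    return enumerate_product_ensemble(emap, np.array([0.9, 0.5]))


@pytest.fixture(scope="session")
def disjunctive_toy() -> WorldEnsemble:
    """Same units and probabilities, threshold 1: either unit suffices."""
    emap = ElectoralMap(("A", "B"), (2, 1), 1)
    return enumerate_product_ensemble(emap, np.array([0.9, 0.5]))


@pytest.fixture(scope="session")
def preset_ensemble() -> WorldEnsemble:
    """A 20,000-world draw from the 2020-style forecast preset."""
    return simulate_forecast(forecast_2020_spec(seed=20201103), 20_000)


@pytest.fixture(scope="session")
def preset_actual(preset_ensemble) -> np.ndarray:
    return presets.actual_world_2020(preset_ensemble.map)


@pytest.fixture(scope="session")
def preset_scores(preset_ensemble, preset_actual) -> pd.DataFrame:
    return score_all(preset_ensemble, preset_actual, cesm_mode="exhaustive")
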