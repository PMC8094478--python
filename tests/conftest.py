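from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import contextcv as cv

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def grid_1to9() -> cv.ContextGrid:
    """3x3 grid of the integers 1..9 (population SD of the window = 2.5820)."""
    return cv.ContextGrid(
        spec=cv.GridSpec(3, 3),
        toxicity=np.arange(1.0, 10.0).reshape(3, 3),
    )


@pytest.fixture
def spike_grid() -> cv.ContextGrid:
    """21x21 zero grid with a single positive spike at the exact centre."""
    tox = np.zeros((21, 21))
    tox[10, 10] = 5.0
    return cv.ContextGrid(spec=cv.GridSpec(21, 21), toxicity=tox)


def random_masked_grid(rng: np.random.Generator, max_side: int = 25) -> cv.ContextGrid:
    """Random grid with a random mask and a sprinkling of exact zeros."""
    n_rows = int(rng.integers(3, max_side + 1))
    n_cols = int(rng.integers(3, max_side + 1))
    tox = rng.uniform(0.0, 5.0, (n_rows, n_cols))
    tox[rng.random((n_rows, n_cols)) < 0.05] = 0.0  # exercise undefined pixels
    mask = rng.random((n_rows, n_cols)) < 0.9
    if not mask.any():
        mask[0, 0] = True
    return cv.ContextGrid(spec=cv.GridSpec(n_rows, n_cols), toxicity=tox, mask=mask)


def random_masked_stack(rng: np.random.Generator, max_side: int = 25,
                        max_years: int = 6) -> cv.YearStack:
    n_years = int(rng.integers(2, max_years + 1))
    base = random_masked_grid(rng, max_side)
    grids = []
    for t in range(n_years):
        tox = rng.uniform(0.0, 5.0, base.spec.shape)
        tox[rng.random(base.spec.shape) < 0.05] = 0.0
        grids.append(
            cv.ContextGrid(spec=base.spec, toxicity=tox, mask=base.mask, year=2000 + t)
        )
    return cv.YearStack(grids)


@pytest.fixture(scope="session")
def default_study() -> cv.SimulatedStudy:
    """One synthetic study under the default scenario, shared across tests."""
    return cv.simulate_study(cv.ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def default_linkage(default_study) -> cv.LinkageTable:
    return cv.link_contacts(default_study.contacts, default_study.stack)
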