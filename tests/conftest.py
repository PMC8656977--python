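import numpy as np
import pandas as pd
import pytest

from hospeff import DMUPanel, SyntheticConfig


def make_panel(inputs: dict, outputs: dict, year: int = 2019) -> DMUPanel:
    """Build a small panel from column dicts keyed by variable name.

    ``inputs``/``outputs`` map column name -> list of values (one per DMU).
    """
    n = len(next(iter(inputs.values())))
    df = pd.DataFrame(
        {
            "dmu_id": [f"D{i + 1}" for i in range(n)],
            "year": [year] * n,
            **inputs,
            **outputs,
        }
    )
    return DMUPanel(df, tuple(inputs), tuple(outputs))


@pytest.fixture
def two_dmu_panel():
    """A(2, 2) efficient, B(4, 2) half as productive: 1 input, 1 output."""
    return make_panel({"x": [2.0, 4.0]}, {"y": [2.0, 2.0]})


@pytest.fixture
def study_config():
    """Study-shaped generator config (39 DMUs x 5 years) under a fixed seed."""
    return SyntheticConfig(seed=1)


@pytest.fixture
def small_config():
    """Small CRS config for fast LP-heavy tests."""
    return SyntheticConfig(n_dmus=10, n_years=2, n_efficient=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
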