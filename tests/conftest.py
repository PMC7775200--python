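import numpy as np
import pandas as pd
import pytest

import lwibench as lw


@pytest.fixture(scope="session")
def default_reference():
    """The default synthetic reference panel and its fitted coefficients."""
    return lw.generate_reference(lw.GeneratorConfig(seed=0))


@pytest.fixture()
def toy_panel():
    """A small complete 4-unit x 3-day panel as a bare DataFrame.

    Values are arbitrary but fixed; the regressor matrix is full rank and
    every unit is observed three times, so both the within and between
    steps of the random-effects fit are well defined.
    """
    rng = np.random.default_rng(12345)
    rows = []
    for unit in range(1, 5):
        for day in range(1, 4):
            rows.append({"unit_id": unit, "day_index": day})
    df = pd.DataFrame(rows)
    for name in lw.BEHAVIOR_VARS:
        df[name] = rng.uniform(0, 1, len(df))
    df["y"] = rng.uniform(0, 1, len(df))
    return df


def make_panel(block: np.ndarray, n_units: int = 1, n_days: int | None = None):
    """Wrap an (n x 8) measured block into a PanelDataset."""
    n = block.shape[0]
    if n_days is None:
        n_days = int(np.ceil(n / n_units))
    units = np.repeat(np.arange(1, n_units + 1), n_days)[:n]
    days = np.tile(np.arange(1, n_days + 1), n_units)[:n]
    df = pd.DataFrame({"unit_id": units, "day_index": days})
    for j, name in enumerate(lw.MEASURED_VARS):
        df[name] = block[:, j]
    return lw.PanelDataset(df, n_units=n_units, n_days=n_days)
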