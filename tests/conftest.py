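import numpy as np
import pandas as pd
import pytest

from gorillaspace import EnergyField, Grid, SimConfig, simulate_movement


@pytest.fixture(scope="session")
def grid():
    return Grid(0.0, 0.0, 500.0, 4, 4)


@pytest.fixture(scope="session")
def uniform_field(grid):
    return EnergyField(grid, np.full((4, 4), 6.0))


@pytest.fixture(scope="session")
def patchy_field(grid):
    """4x4 field with a gradient and one masked cell (no vegetation data)."""
    energy = (np.arange(16, dtype=float).reshape(4, 4)) * 100.0
    energy[3, 3] = np.nan
    return EnergyField(grid, energy)


@pytest.fixture(scope="session")
def small_sim():
    """A short multi-group simulation reused by several test modules."""
    cfg = SimConfig(seed=42, n_groups=4, n_days=60, n_cols=12, n_rows=12,
                    observed_fraction=1.0)
    return simulate_movement(cfg)


def make_fixes(points, group="G0", date="2012-10-01"):
    """Helper: a one-group-one-day fix table from a coordinate list."""
    return pd.DataFrame({
        "group": group,
        "date": pd.Timestamp(date),
        "time": np.arange(len(points)) * 30 + 8 * 3600,
        "x": [p[0] for p in points],
        "y": [p[1] for p in points],
    })
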