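"""Shared fixtures.

The expensive artifacts (parameter screens, the gradient-plate runs, the
surrogate training table) are session-scoped so that unit tests and the
acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from colonyopt import (
    PRESETS,
    GridSpec,
    SeedDisk,
    SeedingConfig,
    build_mapping,
    gradient_field,
    screen_WD,
    simulate_2d,
)

#: coarse screening grid used throughout the tests (8x8 per the scaled-down
#: screening resolution; W grid bottoms at the 1-mm lattice pitch)
W_GRID = np.geomspace(0.5, 10.0, 8)
D_GRID = np.geomspace(0.02, 0.5, 8)


@pytest.fixture(scope="session")
def fig2_screens():
    """The three homogeneous-condition screens: nutrient-poor, nutrient-rich,
    high expansion efficiency."""
    p = PRESETS["fig2"]
    return {
        "poor": screen_WD(p, W_GRID, D_GRID),
        "rich": screen_WD(p.replace(N0=30.0), W_GRID, D_GRID),
        "wet": screen_WD(p.replace(gamma=25.0), W_GRID, D_GRID),
    }


@pytest.fixture(scope="session")
def fig2_mapping():
    """Optimal-pattern mapping over nutrient levels at the fig2 condition."""
    return build_mapping(PRESETS["fig2"], [4.0, 8.0, 16.0, 24.0, 30.0],
                         W_grid=W_GRID, D_grid=D_GRID)


@pytest.fixture(scope="session")
def fig5_mapping():
    """Condition-to-pattern mapping for the gradient-plate parameter set."""
    return build_mapping(PRESETS["fig5"], [0.5, 5.0, 10.0, 15.0, 20.0],
                         W_grid=W_GRID, D_grid=D_GRID)


@pytest.fixture(scope="session")
def gradient_runs(fig5_mapping):
    """Gradient-plate simulations: the screened parameter set and a
    high-expansion-efficiency control."""
    grid = GridSpec(Lx=90.0, Ly=90.0, h=1.0, dt=0.02)
    seeding = SeedingConfig([SeedDisk(center=(45.0, 45.0), radius=5.0, C0=1.6)])
    out = {}
    for name, params in [("fig5", PRESETS["fig5"]),
                         ("high_gamma", PRESETS["fig5"].replace(gamma=25.0))]:
        fld = gradient_field(0.0, 20.0, grid, D_N=params.D_N)
        out[name] = simulate_2d(params, fig5_mapping, fld, seeding, t_end=16.0)
    return out


@pytest.fixture(scope="session")
def training_table():
    """Small simulator-generated training table for the surrogate."""
    from colonyopt.surrogate import build_training_set

    Wg = np.geomspace(0.5, 10.0, 5)
    Dg = np.geomspace(0.02, 0.5, 5)
    return build_training_set(40, Wg, Dg, seed=7)
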