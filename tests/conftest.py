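import numpy as np
import pytest

from trackssm.simulate import SimParams, simulate_accumulation
from trackssm.trajectories import TimeGrid


@pytest.fixture(scope="session")
def default_grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def small_grid() -> TimeGrid:
    """T = 40 with onset at t = 10: fast enough for MCMC in unit tests."""
    return TimeGrid(n_frames=41, onset_velocity_index=10)


@pytest.fixture(scope="session")
def tiny_grid() -> TimeGrid:
    """T = 6 with onset at t = 3: small enough for brute-force oracles."""
    return TimeGrid(n_frames=7, onset_velocity_index=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_trackset(default_grid):
    """A small deterministic accumulation simulation shared across tests."""
    params = SimParams(
        grid=default_grid,
        n_cells=1,
        organelles_per_cell=4,
        initial_distances=[6.0, 10.0, 16.0, 22.0],
        sigma_w=0.2,
        sigma_y=0.2,
        signal_speed=0.8,
        seed=42,
    )
    return simulate_accumulation(params)
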