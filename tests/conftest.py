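import numpy as np
import pytest

from cosmoscreen import (
    EnergyParameters,
    SigmaGrid,
    SigmaSurface,
    fixture_library,
)


@pytest.fixture(scope="session")
def grid():
    return SigmaGrid()


@pytest.fixture(scope="session")
def params():
    return EnergyParameters()


@pytest.fixture(scope="session")
def library(grid):
    """The packaged synthetic fixture cast (EPA + 16 cations + 22 anions)."""
    return fixture_library(grid, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_surface(rng, n_segments=50, formal_charge=0, with_positions=True,
                   compound_id="random"):
    """Seeded random surface satisfying the type invariants."""
    areas = rng.uniform(0.1, 2.0, n_segments)
    sigma = rng.uniform(-0.02, 0.02, n_segments)
    # shift densities so the screening charge mirrors the formal charge
    target = -float(formal_charge)
    sigma += (target - np.dot(areas, sigma)) / areas.sum()
    positions = rng.uniform(-5, 5, (n_segments, 3)) if with_positions else None
    return SigmaSurface(
        compound_id=compound_id,
        areas=areas,
        charge_densities=sigma,
        formal_charge=formal_charge,
        positions=positions,
    )
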