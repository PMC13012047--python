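"""Shared fixtures: worlds and truth runs are expensive, so they are built
once per session and reused read-only across test modules."""

import numpy as np
import pytest

from oceanch4.forcing import gas_exchange_operator
from oceanch4.pipeline import TRUTH_OXIDATION, TRUTH_PRODUCTION, make_truth
from oceanch4.world import WorldConfig, build_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (seed 0)."""
    return build_world(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def gx(world):
    return gas_exchange_operator(world.forcing, world.grid)


@pytest.fixture(scope="session")
def truth_noisy():
    """Known-truth experiment with the default observation noise."""
    return make_truth(seed=11, dt=0.5)


@pytest.fixture(scope="session")
def truth_clean():
    """Noise-free known-truth experiment (same seed as truth_noisy)."""
    return make_truth(seed=11, noise_sd=0.0, dt=0.5)


@pytest.fixture(scope="session")
def still_world():
    """A world with all circulation and mixing switched off (A = 0), for
    closed-form single-cell checks."""
    cfg = WorldConfig(
        nlat=2, nlon=2, nz=2,
        overturning_sv=0.0, gyre_sv=0.0,
        kappa_h=0.0, kappa_v=0.0, kappa_v_polar=0.0,
    )
    return build_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
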