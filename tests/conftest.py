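import numpy as np
import pytest

from uvpool import DoseSchedule, PhotophysicsParams, PoolSpec, simulate_counts


@pytest.fixture(scope="session")
def canonical_params() -> PhotophysicsParams:
    """Canonical dimer-yield table with quenching and secondary kinetics."""
    return PhotophysicsParams.default()


@pytest.fixture(scope="session")
def small_pool_table():
    """A modest seeded octamer pool simulation shared across tests."""
    pool = PoolSpec(depth=200_000, bias_sigma=0.5)
    params = PhotophysicsParams.default()
    schedule = DoseSchedule.log_spaced(10, 250.0)
    return simulate_counts(pool, params, schedule, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
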