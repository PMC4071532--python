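import numpy as np
import pytest

from megafauna.synthetic import (
    DGPParams,
    WorldConfig,
    generate_climate_field,
    generate_regions,
)


@pytest.fixture(scope="session")
def world229():
    """Default-sized world: 229 regions, 6 continents, 30x30 lattice."""
    return generate_regions(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def small_world():
    """Compact world for cheap tests: 24 regions on a 8x9 lattice."""
    cfg = WorldConfig(n_regions=24, grid_shape=(8, 9), cell_size_km=300.0, seed=3)
    return generate_regions(cfg)


@pytest.fixture(scope="session")
def ta229(world229):
    """Standardized temperature-anomaly scores for the 229-region world.

    Built like the pipeline's climate stage: absolute difference between two
    correlated epoch fields (the shared trend cancels), aggregated to regions
    and mapped through the sqrt/max standardization.
    """
    from megafauna.synthetic import generate_epoch_pair

    cfg = WorldConfig(seed=0)
    a, b = generate_epoch_pair(cfg, 600.0, 0.8, seed=11, trend_amplitude=25.0,
                               noise_sd=4.0)
    diff = np.abs(a.values - b.values)
    vals = [diff[world229.membership == rid].mean()
            for rid in world229.table["region_id"]]
    v = np.sqrt(np.asarray(vals))
    return v / v.max()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def table1_params():
    return DGPParams()  # reference beta, lambda=0.6, sigma=0.15
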