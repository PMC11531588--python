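import numpy as np
import pytest

from clamcore.synthetic import SimulationConfig, simulate_bucket


@pytest.fixture(scope="session")
def small_config():
    """A small, fast bucket geometry with the same structure as the full scan."""
    return SimulationConfig(
        grid_nx=60,
        grid_ny=50,
        grid_nz=160,
        surface_z=20,
        multiple_z=130,
        bucket_type="A",
        n_clams=8,
        noise_sigma=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bucket(small_config):
    return simulate_bucket(small_config, bucket_id="A1")


@pytest.fixture(scope="session")
def noiseless_bucket():
    cfg = SimulationConfig(
        grid_nx=60,
        grid_ny=50,
        grid_nz=160,
        surface_z=20,
        multiple_z=130,
        bucket_type="A",
        n_clams=6,
        noise_sigma=0.0,
        seed=3,
    )
    return simulate_bucket(cfg, bucket_id="A9")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
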