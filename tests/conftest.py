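import numpy as np
import pytest

from aed_golden import CityConfig, generate_city, square_region


@pytest.fixture(scope="session")
def default_city():
    """Full-scale synthetic city with the default (clustered) configuration."""
    return generate_city(CityConfig(seed=11))


@pytest.fixture(scope="session")
def small_city():
    """Compact city for fast route-metric tests."""
    return generate_city(CityConfig(
        region=square_region(3000.0), seed=5, n_events=150, n_devices=120,
        grid_spacing=100.0, device_cluster_count=15, anchors_per_type=3,
        event_scatter_sd=200.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
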