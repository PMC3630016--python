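import numpy as np
import pytest

from phenodesign import (
    FieldParams,
    GridLayout,
    UniformityData,
    make_field,
    simulate_uniformity,
)


@pytest.fixture
def zone_layout():
    """The standard 3-lane x 24-position zone (72 carts)."""
    return GridLayout()


@pytest.fixture
def default_zone_data(zone_layout):
    """One simulated uniformity trial with the default calibration."""
    params = FieldParams(seed=42)
    return simulate_uniformity(make_field(zone_layout, params), params)


@pytest.fixture
def trended_zone_data(zone_layout):
    """Uniformity data with a strong west->east trend and lane effects."""
    params = FieldParams(
        pos_slope=1.5, zone_sd=15.0, lane_effects=(-4.0, 0.0, 4.0), seed=7
    )
    return simulate_uniformity(make_field(zone_layout, params), params)


@pytest.fixture
def toy_two_blocks():
    """1x6 strip with values {1,2,3},{4,5,6}: within-block MS 1.0, total 3.5."""
    layout = GridLayout(n_lanes=1, n_positions=6)
    return UniformityData(
        layout=layout, values=np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    )
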