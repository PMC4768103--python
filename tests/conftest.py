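import numpy as np
import pytest

from vortexlcs.flow_io import VelocityField4D
from vortexlcs.synthetic_data import GridSpec


@pytest.fixture
def coarse_grid() -> GridSpec:
    """Cube grid generously covering +-40 mm; coarse is fine for linear fields."""
    return GridSpec(
        shape=(9, 9, 9),
        spacing=(10.0, 10.0, 10.0),
        origin=(-40.0, -40.0, -40.0),
        time_points=np.array([0.0, 400.0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_field(rng) -> VelocityField4D:
    return VelocityField4D(
        velocity=rng.normal(0, 20, size=(5, 6, 7, 8, 3)),
        grid_spacing=(3.0, 3.0, 3.0),
        grid_origin=(-10.0, -9.0, -8.0),
        time_points=np.arange(5) * 50.0,
        venc=150.0,
        cycle_length=1000.0,
    )
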