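import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bifcros.arrays import make_building_block
from bifcros.segmentation import CellMeasurement


@pytest.fixture(scope="session")
def block():
    return make_building_block(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def measurement(values, cell_id=1):
    values = np.asarray(values, dtype=float)
    return CellMeasurement(
        cell_id=cell_id,
        area=values.size,
        pixel_values=values,
        mean_intensity=float(values.mean()),
    )


@pytest.fixture
def make_measurement():
    return measurement
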