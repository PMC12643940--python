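import numpy as np
import pytest

from flowscreen import EventTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """Six events on two channels with easily hand-checked values."""
    return EventTable.from_arrays(
        np.array(
            [
                [100.0, 10.0],
                [200.0, 20.0],
                [300.0, 30.0],
                [400.0, 5.0],
                [50.0, 40.0],
                [150.0, 25.0],
            ]
        ),
        ["CD34", "CD38"],
        sample_id="demo",
    )


def lognormal_table(rng, location, sigma, n, channel="PE", sample_id="sim"):
    x = location * np.exp(sigma * rng.standard_normal(n))
    return EventTable.from_arrays(x[:, None], [channel], sample_id=sample_id)
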