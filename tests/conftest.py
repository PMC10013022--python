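import numpy as np
import pytest

from boldvis import BlockDesignSpec, BoldParams, TimeSeries, make_design


@pytest.fixture
def default_design():
    return make_design(BlockDesignSpec())


@pytest.fixture
def quiet_params():
    """Noise-free, task-free parameters: the generator's deterministic core."""
    return BoldParams(noise_sd=0.0, amplitude_word=0.0, amplitude_nonword=0.0)


def random_series(seed: int, n: int) -> TimeSeries:
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.uniform(0.0, 1.0, size=n))
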