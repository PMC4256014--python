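import numpy as np
import pytest

import retinawave as rw


@pytest.fixture(scope="session")
def params():
    return rw.ModelParams()


@pytest.fixture(scope="session")
def rest(params):
    return rw.find_rest_state(params)


@pytest.fixture(scope="session")
def disk_series():
    from retinawave.fixtures import FixtureWaveSpec, make_disk_wave
    spec = FixtureWaveSpec(sources=[(1.0, 1.0, 0.5)], speed=0.1,
                           burst_duration=0.5, duration=8.0)
    return spec, make_disk_wave(spec)
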