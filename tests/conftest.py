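import numpy as np
import pytest

from neuroloop import AcquisitionParams, generate_schedule
from neuroloop.glm import MICROTIME_RESOLUTION, canonical_hrf


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def hrf(acq):
    return canonical_hrf(acq.tr_seconds / MICROTIME_RESOLUTION, acq.tr_seconds)


@pytest.fixture(scope="session")
def cf_schedule():
    return generate_schedule(8, "CF", seed=11)


@pytest.fixture(scope="session")
def eobf_schedule():
    return generate_schedule(8, "EoBF", seed=11)


@pytest.fixture(scope="session")
def transfer_schedule():
    return generate_schedule(8, "NONE", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
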