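import numpy as np
import pytest

from exoresist import ParticipantProfile


@pytest.fixture
def profile():
    return ParticipantProfile(id="S1", body_mass=50.0)


@pytest.fixture
def asymmetric_profile():
    return ParticipantProfile(
        id="S2", body_mass=50.0, affected_side="left", asymmetry=0.5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
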