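import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dyadsync.ethogram import Ethogram, FreezingBout, SessionLayout


@pytest.fixture
def layout():
    return SessionLayout()


@pytest.fixture
def make_ethogram(layout):
    def _make(subject_id="m1", bouts=((240, 248), (300, 320))):
        return Ethogram(
            subject_id, layout, tuple(FreezingBout(s, e) for s, e in bouts)
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240609)
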