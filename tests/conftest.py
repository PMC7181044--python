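import numpy as np
import pytest

from taupet.frames import default_schedule
from taupet.synth import ReferenceModel, demo_region_set, reference_tac


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def ref_model():
    return ReferenceModel()


@pytest.fixture(scope="session")
def cb_tac(ref_model, schedule):
    """Noiseless frame-averaged cerebellar (reference) TAC."""
    return reference_tac(ref_model, schedule)


@pytest.fixture()
def region_set():
    return demo_region_set(block=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
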