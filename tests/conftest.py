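import numpy as np
import pytest

from is605scan.config import PipelineConfig
from is605scan.realization import default_reference


@pytest.fixture(scope="session")
def ref():
    """The packaged seeded reference realization (built once per session)."""
    return default_reference()


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
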