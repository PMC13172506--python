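import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests: examples derive from the test body, not a
# per-run random seed
settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
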