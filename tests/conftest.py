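import numpy as np
import pytest

from irrnet.synth import fixtures


@pytest.fixture(scope="session")
def toy():
    """Canonical fixture networks T1..T5."""
    return fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20240828)
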