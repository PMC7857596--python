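import numpy as np
import pytest

from mesfinder.references import build_reference_set


@pytest.fixture(scope="session")
def refs():
    """The frozen synthetic reference set (expensive; build once)."""
    return build_reference_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210203)
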