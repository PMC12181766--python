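import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def central_difference(fn, x, h=1e-5):
    """Independent numerical-derivative oracle used against the closed forms."""
    return (fn(x + h) - fn(x - h)) / (2.0 * h)
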