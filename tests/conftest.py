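import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_spd(rng, n, diag_boost=None):
    """Random well-conditioned symmetric positive-definite matrix."""
    a = rng.standard_normal((n, n))
    return a @ a.T + (diag_boost if diag_boost is not None else n) * np.eye(n)


@pytest.fixture
def spd():
    return make_spd
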