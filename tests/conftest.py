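import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_series(rng):
    """Factory for non-degenerate random series of a given length."""

    def make(T: int, scale: float = 1.0, loc: float = 0.0) -> np.ndarray:
        return loc + scale * rng.standard_normal(T)

    return make
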