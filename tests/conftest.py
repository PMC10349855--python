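import numpy as np
import pytest

from prelink.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def bound_complex():
    """Deterministic bound toy complex shared by the suite (read-only)."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def apo_complex():
    return make_toy_complex(ToyComplexSpec(bound=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
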