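import warnings

import numpy as np
import pytest

from lungdose.phantom import (
    generate_phantom,
    morphometry_benchmark_spec,
    spec_from_preset,
)

warnings.filterwarnings("ignore", message=".*threshold.*")


@pytest.fixture(scope="session")
def itli_phantom():
    """Default-scale (128³) instillation phantom shared across tests."""
    return generate_phantom(spec_from_preset("itli", seed=11))


@pytest.fixture(scope="session")
def fast_phantom():
    """Second instillation phantom for structural assertions."""
    return generate_phantom(spec_from_preset("itli", seed=7))


@pytest.fixture(scope="session")
def uniform_phantom():
    return generate_phantom(spec_from_preset("uniform", seed=5))


@pytest.fixture(scope="session")
def morpho_phantom():
    """Well-resolved benchmark phantom for tree-recovery tests."""
    return generate_phantom(morphometry_benchmark_spec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
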