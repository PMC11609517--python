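import numpy as np
import pytest

from octaplex.phantoms import generate_cohort, generate_phantom_volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_volume():
    """One deterministic 64x64x96 phantom cube with boundaries."""
    g = np.random.default_rng(1)
    return generate_phantom_volume("p01", "OD", (64, 64, 96), g)


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients, one or two cubes each, 48 px (kept small for speed)."""
    return generate_cohort(6, (1, 2), (48, 48, 64), seed=11)
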