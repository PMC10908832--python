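import numpy as np
import pytest

from niistego import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom16():
    """Seeded 64x64x16 uint16 phantom shared by the slower codec tests."""
    return generate_phantom(PhantomSpec(shape=(64, 64, 16), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
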