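import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_population():
    """A moderately sized Beta(1,1) population shared across read-only tests."""
    import microprivacy as mp

    return mp.sample_population(t=2000, pi1=1.0, pi2=1.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
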