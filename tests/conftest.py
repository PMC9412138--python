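import numpy as np
import pytest

from conchmetrics import CoilParams, OrnamentParams, generate_pair, make_primitive


@pytest.fixture(scope="session")
def cube():
    return make_primitive("cube")


@pytest.fixture(scope="session")
def icosphere():
    """Unit sphere, subdivision 4: 5120 faces, area within 0.3% of 4*pi."""
    return make_primitive("icosphere", radius=1.0, subdivisions=4)


@pytest.fixture(scope="session")
def hemisphere():
    return make_primitive("hemisphere", radius=1.0)


@pytest.fixture(scope="session")
def flat_patch():
    return make_primitive("flat_patch", size_x=1.0, size_y=1.0)


@pytest.fixture(scope="session")
def small_coil():
    """Coarse conch for fast batch tests (~12k faces)."""
    return CoilParams(steps_per_whorl=64, sections=32)


@pytest.fixture(scope="session")
def ribbed_pair(small_coil):
    return generate_pair(small_coil, OrnamentParams(seed=11, rib_amplitude=0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20221)
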