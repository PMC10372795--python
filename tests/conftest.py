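import numpy as np
import pytest

from etem.phantoms import PhantomSpec, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20230713)


@pytest.fixture(scope="session")
def ct_mri_small():
    """64x64 ct-mri phantom pair for fast pipeline tests."""
    return make_pair(PhantomSpec(kind="ct-mri", size=64, seed=11))


@pytest.fixture(scope="session")
def ct_mri_128():
    return make_pair(PhantomSpec(kind="ct-mri", size=128, seed=11))


@pytest.fixture(scope="session")
def step_texture_pair():
    return make_pair(PhantomSpec(kind="step-texture", size=96, seed=5,
                                 texture_amplitude=0.05))
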