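import numpy as np
import pytest

from gwdemons.phantoms import PhantomSpec, SyntheticWarp, make_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def translation_pair():
    """128x128 phantom pair displaced by a 3-px row translation."""
    spec = PhantomSpec(seed=7)
    warp = SyntheticWarp(kind="translation", magnitude=3.0, direction=(1.0, 0.0))
    return make_phantom_pair(spec, warp)


@pytest.fixture(scope="session")
def bump_pair_96():
    """96x96 phantom pair under a 4-px gaussian-bump deformation."""
    spec = PhantomSpec(size=(96, 96), seed=3)
    warp = SyntheticWarp(kind="gaussian_bump", magnitude=4.0)
    return make_phantom_pair(spec, warp)
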