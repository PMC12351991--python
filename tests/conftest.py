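import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from esunet.io import Sample, normalize_volume
from esunet.phantoms import PhantomSpec, make_fixture_suite, make_phantom


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(seed=11)


@pytest.fixture(scope="session")
def one_lesion(suite):
    return suite["one_lesion"]


@pytest.fixture(scope="session")
def two_lesions(suite):
    return suite["two_lesions"]


@pytest.fixture(scope="session")
def small_phantom():
    """32-cube normalized phantom used by the network/training tests."""
    spec = PhantomSpec(shape=(32, 32, 32), n_lesions=1,
                       lesion_radius_range=(4.0, 6.0), seed=3)
    return normalize_volume(make_phantom(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_mask_pair(rng, shape=(6, 6, 6), p=0.3):
    pred = (rng.uniform(size=shape) < p).astype(np.int8)
    gt = (rng.uniform(size=shape) < p).astype(np.int8)
    return pred, gt
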