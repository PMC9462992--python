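import numpy as np
import pytest

from aopmeter import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_spec():
    """Default desk-scale phantom spec (96x96)."""
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def standard_sample(desk_spec):
    return phantom.generate_standard(desk_spec, "P000", 42)


def random_blob_mask(rng, shape=(12, 12), n_seeds=3, label=2):
    """Small random connected-ish foreground mask for loss fixtures."""
    from scipy import ndimage
    m = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_seeds):
        y, x = rng.integers(2, shape[0] - 2), rng.integers(2, shape[1] - 2)
        m[max(y - 2, 0):y + 3, max(x - 2, 0):x + 3] = label
    m = ndimage.binary_closing(m == label).astype(np.uint8) * label
    return m
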