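import numpy as np
import pytest

from qdaseg.mri_io import Volume, volume_to_slices
from qdaseg.phantom import PhantomSpec, generate, tumor_truth

SMALL_SHAPE = (96, 96, 12)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact single-tumor phantom shared across tests."""
    spec = PhantomSpec(
        shape=SMALL_SHAPE, tumor_radius_range=(6.0, 9.0), seed=11
    )
    vol, labels = generate(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def tumor_slice(small_phantom):
    """The slice with the largest tumor cross-section, plus its truths."""
    _, vol, labels = small_phantom
    truth = tumor_truth(labels)
    k = int(np.argmax(truth.sum(axis=(0, 1))))
    sl = volume_to_slices(vol)[k]
    return sl, truth[:, :, k], labels.data[:, :, k]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_blob_mask(rng, shape=(40, 40), smooth=2.2, q=0.72):
    """Random smooth blobs for boundary/metric oracles."""
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.normal(size=shape), smooth)
    m = f > np.quantile(f, q)
    return ndimage.binary_opening(m, structure=np.ones((3, 3)))
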