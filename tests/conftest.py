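import numpy as np
import pytest

from boutondetect import SceneParams, train_from_synthetic
from boutondetect.imaging_io import Image2D


@pytest.fixture(scope="session")
def default_model():
    """SVM trained once on 450 + 450 synthetic patches (seed 7)."""
    return train_from_synthetic(SceneParams(seed=7), n_per_class=450, split_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def gaussian_blob_image(
    shape=(201, 201), centre=(100, 100), sd=4.0, amplitude=100.0, background=0.0
) -> Image2D:
    """A single isotropic Gaussian blob on a flat background."""
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r2 = (y - centre[0]) ** 2 + (x - centre[1]) ** 2
    return Image2D(background + amplitude * np.exp(-r2 / (2 * sd * sd)))


def disc_image(shape, centre, radius, amplitude=1.0) -> Image2D:
    """A filled bright disc (hard-edged blob) on zero background."""
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r2 = (y - centre[0]) ** 2 + (x - centre[1]) ** 2
    return Image2D(np.where(r2 <= radius**2, amplitude, 0.0))
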