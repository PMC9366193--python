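import numpy as np
import pytest

from boundaryseg import PhantomSpec, extract_coarse_contour, filter_two_per_column


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_spec():
    return PhantomSpec(seed=11)


@pytest.fixture
def ellipse_mask():
    """Filled axis-aligned ellipse, semi-axes 20 (cols) x 12 (rows), centre (32, 32)."""
    gy, gx = np.mgrid[0:64, 0:64]
    return ((((gx - 32) / 20.0) ** 2 + ((gy - 32) / 12.0) ** 2) <= 1.0).astype(np.uint8)


@pytest.fixture
def square_mask():
    """Filled 20x20 square inside a 64x64 raster."""
    m = np.zeros((64, 64), dtype=np.uint8)
    m[20:40, 20:40] = 1
    return m


@pytest.fixture
def ellipse_contour(ellipse_mask):
    return extract_coarse_contour(ellipse_mask)


@pytest.fixture
def ellipse_filtered(ellipse_contour):
    return filter_two_per_column(ellipse_contour)


def random_blob_mask(rng, size=16, p=0.5):
    """Unstructured random binary mask (for morphology property tests)."""
    return (rng.random((size, size)) < p).astype(np.uint8)
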