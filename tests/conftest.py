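import numpy as np
import pytest

from livertex.io import QuantizedRoi, RoiImage
from livertex.synthetic import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return PhantomSpec(seed=7)


@pytest.fixture
def small_roi(rng):
    """A 32x32 noisy ROI with an off-center circular mask."""
    pixels = 100 + 20 * rng.standard_normal((32, 32))
    rr, cc = np.mgrid[0:32, 0:32]
    mask = (rr - 15) ** 2 + (cc - 17) ** 2 <= 100
    return RoiImage(pixels, mask, subject_id="small")


def quantized_from_levels(levels: np.ndarray, n_levels: int) -> QuantizedRoi:
    """Wrap a hand-written level array (0 = out of mask) as a QuantizedRoi."""
    levels = np.asarray(levels, dtype=np.int64)
    return QuantizedRoi(levels=levels, mask=levels > 0, range=n_levels)
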