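import numpy as np
import pytest

from sasus.synthetic import PhantomSpec, generate_phantom
from sasus.types import Sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(n: int, cy: float, cx: float, r: float) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n]
    return ((rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2).astype(np.uint8)


def ellipse_mask(n: int, cy: float, cx: float, a: float, b: float) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n]
    return (((rows - cy) / a) ** 2 + ((cols - cx) / b) ** 2 <= 1.0).astype(np.uint8)


def make_sample(mask: np.ndarray, rng=None, size_class=None) -> Sample:
    if rng is None:
        rng = np.random.default_rng(0)
    img = np.clip(rng.uniform(0.1, 0.9, size=mask.shape) * 0.5
                  + 0.3 * mask, 0.0, 1.0)
    ratio = float(mask.sum()) / mask.size
    return Sample(image=img, mask=mask.astype(np.uint8),
                  original_area_ratio=ratio, size_class=size_class)


@pytest.fixture
def small_phantom(rng):
    spec = PhantomSpec(canvas=96, viewport="sector", target_area_ratio=0.05)
    return generate_phantom(spec, rng)
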