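import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from petharm import (
    FrameSchedule,
    Image3D,
    PhantomSpec,
    ReferenceShape,
    make_reference_tac,
    make_uniform_phantom,
)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_dynamic()


@pytest.fixture(scope="session")
def ref_shape():
    return ReferenceShape()


@pytest.fixture(scope="session")
def ref_tac(ref_shape, schedule):
    return make_reference_tac(ref_shape, schedule)


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth positive test image with zero boundary (a Gaussian bump),
    61^3 at 1 mm, for blur/interpolation properties."""
    n = 61
    x = np.arange(n) - (n - 1) / 2
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    vals = 1000.0 * np.exp(-(xx**2 + yy**2 + zz**2) / (2 * 8.0**2))
    return Image3D(vals, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def phantom():
    img, mask = make_uniform_phantom(PhantomSpec())
    return img, mask
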