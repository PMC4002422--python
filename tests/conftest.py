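import numpy as np
import pytest

from speckletex.phantom import PhantomSpec, generate_phantom
from speckletex.types import ImageStack, RoiMask


@pytest.fixture(scope="session")
def control_stack() -> ImageStack:
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), seed=11))


@pytest.fixture(scope="session")
def degenerate_stack() -> ImageStack:
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), seed=11, degeneration=1.0))


@pytest.fixture()
def full_roi():
    def _make(shape):
        return RoiMask(mask=np.ones(shape, dtype=bool))

    return _make


@pytest.fixture()
def constant_stack() -> ImageStack:
    return ImageStack(voxels=np.full((16, 16, 16), 100, dtype=np.uint8))
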