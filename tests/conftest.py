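import numpy as np
import pytest

from bonematrix.calibration import default_map


@pytest.fixture(scope="session")
def cal():
    """Package-default calibration (GL 25 <-> 0.0 wt%, GL 55 <-> 5.2 wt%)."""
    return default_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210537)


def make_gl_image(cal, ca_values, shape=None):
    """Quantize an array of Ca values into an 8-bit gray-level raster."""
    gl = cal.ca_to_gl(np.asarray(ca_values, dtype=float), clip=True)
    img = np.clip(np.rint(gl), 0, 255).astype(np.uint8)
    return img.reshape(shape) if shape is not None else img
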