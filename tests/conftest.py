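import numpy as np
import pytest

from photomem import imaging_contour as ic


@pytest.fixture
def angles256():
    return ic.uniform_angles(256)


@pytest.fixture
def ellipse_contour(angles256):
    """Axis-aligned ellipse a=10 um, b=8 um as a polar contour."""
    a, b = 10e-6, 8e-6
    r = a * b / np.sqrt((b * np.cos(angles256)) ** 2 + (a * np.sin(angles256)) ** 2)
    return ic.VesicleContour(angles=angles256, radii=r), a, b
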