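import numpy as np
import pytest

from qpicd.core import PhaseImage
from qpicd.synthetic import CellPhantomSpec, CohortConfig, SigmoidParams

PIXEL = 0.48
LAMBDA = 0.532


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_phase(array, pixel_size=PIXEL, wavelength=LAMBDA):
    return PhaseImage(np.asarray(array, dtype=float), pixel_size, wavelength)


@pytest.fixture
def two_level_cell():
    """1000-px rectangular cell: 500 px periphery at 1 rad, 500 px centre at 3 rad."""
    phase = np.zeros((60, 60))
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:35] = True  # 40 x 25 = 1000 px
    phase[10:50, 10:35] = 1.0
    phase[10:30, 10:35] = 3.0  # 20 x 25 = 500 px central block
    return make_phase(phase), mask


@pytest.fixture
def disc_mask():
    yy, xx = np.mgrid[0:128, 0:128]
    return (xx - 64.0) ** 2 + (yy - 64.0) ** 2 <= 50.0**2


def simple_spec(class_label="normal", **overrides) -> CellPhantomSpec:
    defaults = dict(
        class_label=class_label,
        center=(23.04, 23.04),  # grid centre of 96 px at 0.48 um
        initial_radius=10.0,
        central_fraction=0.2,
        peripheral_phase=1.0,
        central_phase=3.0,
        axis_ratio=1.0,
        circularity0=1.0,
        dynamics={},
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return CellPhantomSpec(**defaults)


@pytest.fixture
def apoptotic_ring_spec():
    return simple_spec(
        "apoptotic",
        axis_ratio=1 / 1.5,
        dynamics={"nuclear_edge_score": SigmoidParams(0.8, 3.0, 1.0)},
    )
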