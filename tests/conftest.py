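import numpy as np
import pytest

from dynmrs.io import AcquisitionGrid, BasisSet
from dynmrs.synthetic import PseudoBasisSpec


@pytest.fixture
def grid():
    return AcquisitionGrid(
        dwell_time=2e-3, n_points=256, spectrometer_freq=123.2, ppm_reference=3.0
    )


@pytest.fixture
def fine_grid():
    """High-resolution grid for lineshape measurements (0.49 Hz/bin)."""
    return AcquisitionGrid(
        dwell_time=2e-3, n_points=1024, spectrometer_freq=123.2, ppm_reference=3.0
    )


@pytest.fixture
def singlet_basis(fine_grid):
    spec = PseudoBasisSpec({"peak": [(3.0, 1.0, 0.0)]}, linewidth_hz=2.0)
    return spec.build(fine_grid)


@pytest.fixture
def two_peak(grid):
    spec = PseudoBasisSpec(
        {"A": [(2.9, 1.0, 0.0)], "B": [(3.1, 1.0, 0.0)]}, linewidth_hz=2.0
    )
    return spec.build(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
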