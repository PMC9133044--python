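import numpy as np
import pytest

from duratrace import synthgen as sg


@pytest.fixture
def imaging_clean():
    """Noise-free acquisition at the standard confocal geometry."""
    return sg.ImagingSpec(gaussian_sd=0.0, psf_sigma=1.0, background_level=10.0)


@pytest.fixture
def tube_stack(imaging_clean):
    """A noise-free 200 µm straight tube phantom with its truth."""
    truth = sg.straight_tube_truth(200.0, radius_um=2.0, start_um=(12.0, 22.0, 2.0))
    stack = sg.rasterize_neurites(truth, imaging_clean, (5, 40, 200))
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
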