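import math

import numpy as np
import pytest

from coccoloc import ImagingSpec


@pytest.fixture
def noise_free_imaging():
    """Imaging chain with no blur, no shot noise, no read noise."""
    return ImagingSpec(psf_sigma_px=0.0, photon_scale=math.inf, read_noise_sd=0.0, bit_depth=16)


@pytest.fixture
def blur_only_imaging():
    """Diffraction-limited blur without any noise (ideal optics test case)."""
    return ImagingSpec(psf_sigma_px=1.6, photon_scale=math.inf, read_noise_sd=0.0, bit_depth=16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
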