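import numpy as np
import pytest

from psoct import ImagingConfig, make_bladder_model, simulate_bscan
from psoct.simulate import NoiseModel


@pytest.fixture
def config():
    """Full-depth scan geometry covering the bladder design stack."""
    return ImagingConfig()


@pytest.fixture
def small_config():
    """Short scan geometry for slab tests (keeps arrays small)."""
    return ImagingConfig(depth_pixels=420, lateral_pixels=64)


@pytest.fixture
def tilt_profile(config):
    """Linear surface ramp, 30 -> 80 um across the scan width."""
    return np.linspace(30.0, 80.0, config.lateral_pixels)


@pytest.fixture
def normal_pair_clean(config, tilt_profile):
    """Noise-free normal-bladder B-scan with a tilted surface."""
    model = make_bladder_model("normal", surface_profile=tilt_profile)
    return simulate_bscan(model, config, NoiseModel.off())
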