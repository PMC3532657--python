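import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from residuoscope import AcquisitionSpec


@pytest.fixture
def small_spec() -> AcquisitionSpec:
    """A compact sensor used by most image tests (noise defaults on par
    with a cooled interline CCD)."""
    return AcquisitionSpec(
        pixel_pitch_um=6.5,
        frame_shape=(120, 160),
        exposure_time_ms=100.0,
        read_noise_sd=2.0,
        dark_offset=100.0,
    )


@pytest.fixture
def noiseless_spec() -> AcquisitionSpec:
    return AcquisitionSpec(
        pixel_pitch_um=6.5,
        frame_shape=(120, 160),
        exposure_time_ms=100.0,
        read_noise_sd=0.0,
        dark_offset=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
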