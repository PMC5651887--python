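import numpy as np
import pytest

from embryoraman import synthetic
from embryoraman.io_formats import Spectrum


def gaussian(axis, center, sigma, amplitude):
    return amplitude * np.exp(-((axis - center) ** 2) / (2.0 * sigma**2))


@pytest.fixture
def axis():
    return np.linspace(600.0, 1800.0, 1201)


@pytest.fixture
def clean_single_band_config():
    """Noise-free, spike-free, baseline-free config with one 900 cm^-1 band."""
    return synthetic.SimConfig(
        noise_sd=0.0,
        spike_rate=0.0,
        baseline_coeffs=(0.0, 0.0, 0.0, 0.0),
        water_profile=(),
        band_library=(synthetic.BandSpec(900.0, 8.0, 1.0),),
        effect_size=1.0,
    )


@pytest.fixture
def default_cohort():
    cfg = synthetic.SimConfig(seed=0)
    cohort, truths = synthetic.generate_cohort(cfg)
    toluene, water = synthetic.generate_references(cfg)
    return cfg, cohort, truths, toluene, water


def make_spectrum(axis, intensity, sample_id="s"):
    return Spectrum(sample_id, axis, intensity)
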