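import numpy as np
import pytest

from gaitforce.synthetic import GaitProfileParams, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, perfectly periodic, symmetric 60 s subject."""
    params = GaitProfileParams(
        seed=5, walk_duration_s=60.0, sensor_noise_sd_n=0.0,
        stride_time_cv_pct=0.0, asymmetry_offset_ms=0.0)
    trace, meta, gt = simulate_subject(params)
    return params, trace, meta, gt


@pytest.fixture(scope="session")
def noisy_subject():
    """Realistic subject: timing variability, asymmetry, noise, turns."""
    params = GaitProfileParams(
        seed=11, walk_duration_s=90.0, sensor_noise_sd_n=2.0,
        stride_time_cv_pct=2.2, asymmetry_offset_ms=25.0, turn_every_s=22.0)
    trace, meta, gt = simulate_subject(params)
    return params, trace, meta, gt
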