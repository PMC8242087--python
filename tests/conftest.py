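import numpy as np
import pytest

from diffbp import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free constant-BP record configuration."""
    return SynthConfig(
        seed=11, n_beats=10, noise_sd=0.0, wander_amp=0.0,
        sbp_values=[120.0] * 10, dbp_values=[80.0] * 10,
        hr_values=[60.0] * 10,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def varied_record():
    """Noise-free record with beat-to-beat BP/HR variation."""
    return generate_record(
        SynthConfig(seed=7, n_beats=60, noise_sd=0.0, wander_amp=0.0)
    )
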