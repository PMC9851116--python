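import numpy as np
import pytest

from fvepnet.synth import WaveformParams, generate_dataset, generate_record


@pytest.fixture(scope="session")
def zero_noise_params():
    return WaveformParams(
        noise_std=0.0, drift_amplitude=0.0, baseline_offset_std=0.0, late_wave_std=0.0
    )


@pytest.fixture(scope="session")
def zero_noise_pair(zero_noise_params):
    """Matched noiseless normal/RP sweeps (same latencies, damped P2)."""
    import dataclasses

    normal = generate_record("normal", zero_noise_params, 0, age=40)
    rp = generate_record(
        "rp", dataclasses.replace(zero_noise_params, rp_p2_attenuation=0.3), 0, age=40
    )
    return normal, rp


@pytest.fixture(scope="session")
def small_dataset():
    """200 records (25 normal + 25 RP patients) at default conditions."""
    return generate_dataset({"normal": 25, "rp": 25}, WaveformParams(), rng_seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
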