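import warnings

import pytest

import udilab as u


@pytest.fixture(scope="session")
def sham_low_noise():
    """Default-preset sham recording, low noise, no trapped voids."""
    params = u.SimParams(seed=11, noise_sd=0.05, void_trap_probability=0.0)
    rec, truth = u.simulate_recording(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def sci_low_noise():
    params = u.PRESETS["sci-5000hz"].replace(seed=7, noise_sd=0.05)
    rec, truth = u.simulate_recording(params)
    return params, rec, truth


@pytest.fixture(autouse=True)
def _quiet_band_clip():
    """The 10-10000 Hz acquisition band always clips at a 5 kHz rate."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="band upper edge clipped")
        yield
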