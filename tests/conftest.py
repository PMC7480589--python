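import numpy as np
import pytest

from evsort.simulate import GeneratorConfig, generate_cells


@pytest.fixture(scope="session")
def small_cohort():
    """120 labelled cells (60/60), generator defaults, fixed seed."""
    pixels, labels, gts = generate_cells(60, 60, seed=123)
    return pixels, labels, gts


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator config with the camera noise switched off."""
    return GeneratorConfig(read_noise_sd=0.0, photon_gain=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
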