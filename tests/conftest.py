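import numpy as np
import pytest

import spiralmap as sm


@pytest.fixture(scope="session")
def design():
    return sm.default_design()


@pytest.fixture(scope="session")
def small_design():
    """A 1.5-turn miniature spiral (~1.2 cm path) for fast raster tests."""
    return sm.build_spiral(200.0, 400.0, 1.5, 800.0)


@pytest.fixture(scope="session")
def noiseless_recording(design):
    """Noiseless 2 Hz paced recording at 20 cm/s, APD80 150 ms."""
    config = sm.SimulationConfig(
        cv_true=20.0,
        apd80_true=150.0,
        noise_sd=0.0,
        bleach_rate=0.0,
        seed=11,
    )
    movie = sm.simulate_spiral_recording(design, config)
    return config, movie


@pytest.fixture(scope="session")
def default_noise_recording(design):
    """Default-noise recording used by several analysis tests."""
    config = sm.SimulationConfig(cv_true=20.0, apd80_true=150.0, seed=7)
    movie = sm.simulate_spiral_recording(design, config)
    return config, movie


@pytest.fixture(scope="session")
def atrial_features():
    return sm.APFeatures(
        mdp=-63.9, apa=110.0, dvdt_max=27.1, apd50=294.6 / 1.34, apd90=294.6
    )
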