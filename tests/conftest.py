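import numpy as np
import pytest

from icdep import ica, synthdata as sd


@pytest.fixture(scope="session")
def sim_delay5():
    """Low-noise two-ROI dataset, 5 s inter-ROI delay (the easy regime)."""
    cfg = sd.config_for_cell(delay=5.0, noise_sigma=0.0033, seed=0)
    seq, truth = sd.simulate(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def decomp_delay5(sim_delay5):
    _, seq, _ = sim_delay5
    return ica.decompose(seq, 5, seed=0)


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = sd.config_for_cell(delay=5.0, noise_sigma=0.0, seed=0)
    seq, truth = sd.simulate(cfg)
    return cfg, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
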