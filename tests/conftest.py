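import numpy as np
import pytest

from smdecode.kinetic_model import DecodingModel, StateSpec, load_preset
from smdecode.simulate import SimulationConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cognate25():
    return load_preset("cognate-25C")


@pytest.fixture(scope="session")
def gtpys():
    return load_preset("cognate-25C-GTPyS")


@pytest.fixture()
def two_state():
    """Minimal reversible two-state model (k12 = 2, k21 = 1 s^-1)."""
    return DecodingModel(
        states=[StateSpec("Unbound", 0.0, 0.0), StateSpec("AC", 0.74, 0.06)],
        rates={("Unbound", "AC"): 2.0, ("AC", "Unbound"): 1.0},
    )


@pytest.fixture()
def clean_config():
    """Noise-free, photophysics-free acquisition settings."""
    return SimulationConfig(
        frame_interval=0.010,
        n_frames=600,
        noise_sd=0.0,
        crosstalk_alpha=0.0,
        gamma=1.0,
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        blink_on_rate=0.0,
        static_heterogeneity=False,
        seed=1,
    )
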