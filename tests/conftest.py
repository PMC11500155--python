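import numpy as np
import pytest

import conepulse as cp


@pytest.fixture(scope="session")
def pulsating_preset():
    return cp.make_preset(4.0)


@pytest.fixture(scope="session")
def short_train(pulsating_preset):
    """0.2 s pulsating emission train (≈384 cycles at 1.92 kHz)."""
    return cp.generate_emission_train(pulsating_preset, 0.2, seed=11)


@pytest.fixture(scope="session")
def short_stack(short_train, pulsating_preset):
    """Noiseless 0.2 s online stack (1000 frames at 5 kfps)."""
    settings = cp.AcquisitionSettings(frame_rate=5000, duration=0.2)
    return cp.render_shadowgraph_stack(
        short_train, settings, pulsating_preset, seed=11, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def default_geometry(pulsating_preset):
    return cp.geometry_for_preset(pulsating_preset)
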