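import numpy as np
import pytest

import gammaflow as gf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Two coupled electrodes, small but long enough for TE estimation."""
    return gf.SyntheticConfig(
        n_rows=1, n_cols=2, spacing_mm=1.0, n_trials=8, n_scenes=8,
        phase_noise_sd=0.3, direction_schedule=0.0,
        coupling_edges=(gf.CouplingEdge(0, 1, 1.2, 10.0),), seed=42)


@pytest.fixture
def tiny_session(tiny_config):
    session, truth = gf.generate_session(tiny_config)
    return session
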