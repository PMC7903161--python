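import numpy as np
import pytest

from sass.preprocess import FilterSpec, design_fir
from sass.synth import SessionConfig, generate_session

BAND = (9.0, 11.0)
FS = 500.0


@pytest.fixture(scope="session")
def band_kernel():
    return design_fir(FilterSpec(*BAND), FS)


@pytest.fixture(scope="session")
def small_session():
    """Cheap 16-channel session pair for plumbing-level tests."""
    cfg = SessionConfig(n_channels=16, n_trials=30, seed=7)
    no_stim, stim, truth = generate_session(cfg)
    return cfg, no_stim, stim, truth


@pytest.fixture(scope="session")
def recovery_session():
    """Longer session used for artifact-removal and recovery tests."""
    cfg = SessionConfig(n_channels=16, n_trials=120, seed=11)
    no_stim, stim, truth = generate_session(cfg)
    return cfg, no_stim, stim, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
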