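import numpy as np
import pytest

from kneesim.synthetic import KneeGenConfig, generate_knee


@pytest.fixture(scope="session")
def default_model():
    """The default synthetic knee (seed 42), generator validation included."""
    return generate_knee(KneeGenConfig(seed=42))


@pytest.fixture(scope="session")
def symmetric_model():
    """Exactly mirror-symmetric validation knee."""
    return generate_knee(KneeGenConfig(seed=42, symmetric=True))


@pytest.fixture(scope="session")
def fast_model(default_model):
    """Default knee with a coarser contact grid for plumbing-level tests."""
    from dataclasses import replace

    return replace(default_model, contact_grid_n=16, pfj_grid_n=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
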