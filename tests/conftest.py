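import numpy as np
import pytest

from hccmil.simulate import SlideSimConfig, generate_cohort_bags, generate_nuclei_tile


@pytest.fixture(scope="session")
def small_tile():
    """One deterministic low-risk 64-px tile with mask and nucleus specs."""
    cfg = SlideSimConfig(tile_size=64, seed=3)
    return generate_nuclei_tile(cfg, "low", False, seed=123)


@pytest.fixture(scope="session")
def tiny_bags():
    """A small balanced cohort of 8 bags (8 tiles of 32 px) for fast tests."""
    cfg = SlideSimConfig(n_tiles=8, tile_size=32, signal_fraction=0.5, seed=5)
    return generate_cohort_bags(4, cfg, seed=50)


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (no cross-test state)."""
    return np.random.default_rng(0)
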