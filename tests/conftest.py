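import numpy as np
import pytest

from lickchoice import SimConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small but structurally complete simulator configuration."""
    return SimConfig(n_cells=24, trials_per_session=30, sessions_per_bin=1,
                     seed=7)


@pytest.fixture(scope="session")
def expert_session(tiny_cfg):
    """A bin-6 (experienced) session with strong planted modulation."""
    session, truth = generate_session(tiny_cfg, bin_index=6,
                                      rng=np.random.default_rng(42))
    return session, truth


@pytest.fixture(scope="session")
def null_session(tiny_cfg):
    """A session with every planted modulation switched off."""
    session, truth = generate_session(tiny_cfg.null(), bin_index=6,
                                      rng=np.random.default_rng(43))
    return session, truth
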