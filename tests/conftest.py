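import numpy as np
import pytest

from granupls.simulate import SimConfig, simulate_campaign


@pytest.fixture(scope="session")
def small_campaign():
    """A fast 3-batch clean campaign shared across read-only tests."""
    cfg = SimConfig(n_batches=3, rows_per_batch=(60, 90), seed=7)
    campaign, truths = simulate_campaign(cfg)
    return campaign, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
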