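import numpy as np
import pytest

from riskscape.synthetic import WorldConfig, make_landscape, true_risk_rasters


@pytest.fixture(scope="session")
def small_world():
    """One modest landscape shared across read-only tests."""
    cfg = WorldConfig(seed=101, n_days=20, n_seals=8,
                      extent=(0.0, 400.0, 0.0, 400.0))
    stack = make_landscape(cfg)
    true_risk_rasters(stack, cfg.truth)
    return cfg, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
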