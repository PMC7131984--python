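import numpy as np
import pytest

import reachsim as rs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def basic_config():
    return rs.TaskConfig(variant="center_out", amp_threshold=0.9, session_ms=60_000)


@pytest.fixture
def noiseless_params():
    return rs.AgentParams(jitter_sd=0.0, blip_rate=0.0, revup_prob=0.0)


@pytest.fixture
def short_session():
    """A 60-s seeded closed-loop session with the default synthetic mouse."""
    cfg = rs.TaskConfig(variant="center_out", amp_threshold=0.9, session_ms=60_000)
    return rs.run_session(cfg, rs.SyntheticMouse(rs.AgentParams()), 42)
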