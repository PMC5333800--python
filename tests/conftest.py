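import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170302)


@pytest.fixture(scope="session")
def default_literature():
    """One simulated literature under default conditions, shared by tests."""
    from litpower.synthetic import SyntheticConfig, simulate_literature

    cfg = SyntheticConfig(n_studies=20_000, seed=7)
    records, truth = simulate_literature(cfg)
    return cfg, records, truth
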