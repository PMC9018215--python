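import json

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hyperlpa import sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One full fixture set shared by the read-only tests."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = sim.write_fixtures(out, seed=7)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_115)
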