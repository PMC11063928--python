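import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchrep import (
    ExpressionSimConfig,
    RepertoireSimConfig,
    simulate_expression,
    simulate_repertoire,
    write_fixtures,
)

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_repertoire():
    """The default 50-lineage / 1500-heavy-chain repertoire plus truth."""
    return simulate_repertoire(RepertoireSimConfig())


@pytest.fixture(scope="session")
def default_expression():
    """The default simulated count matrix plus truth."""
    return simulate_expression(ExpressionSimConfig())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixtures(out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
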