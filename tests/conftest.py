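import numpy as np
import pytest

from sugarporter.synthetic import (
    ExpressionConfig,
    FamilyConfig,
    simulate_expression,
    simulate_family,
)

# fixed study seeds; every stochastic test derives from these
FAMILY_SEED = 202
EXPRESSION_SEED = 303


@pytest.fixture(scope="session")
def family():
    """Default synthetic transporter family (shared, read-only)."""
    return simulate_family(FamilyConfig(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def expression_study():
    """Default synthetic expression study (shared, read-only)."""
    return simulate_expression(ExpressionConfig(seed=EXPRESSION_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
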