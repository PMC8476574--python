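import numpy as np
import pytest

from spatialpheno import (
    SimulationConfig,
    generate_expression_cohort,
    train_classifier,
)


@pytest.fixture(scope="session")
def discovery_cohort():
    """Standard synthetic discovery cohort (30/phenotype, effect 2.0, sd 1.0)."""
    return generate_expression_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def trained_model(discovery_cohort):
    return train_classifier(discovery_cohort)


@pytest.fixture(scope="session")
def validation_cohort():
    """Held-out cohort from a disjoint seed, same generating conditions."""
    return generate_expression_cohort(SimulationConfig(seed=12))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
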