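import numpy as np
import pytest

import neuroage as na


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale study configuration shared across module tests."""
    return na.SimulationConfig(n_training=200, n_per_group=(40, 40, 40), seed=11)


@pytest.fixture(scope="session")
def training_table(small_cfg):
    table, truth = na.simulate_training_cohort(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def clinical_table(small_cfg):
    table, truth = na.simulate_clinical_cohort(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_gpr(training_table):
    """GP age model fitted once on the reduced training cohort."""
    table, _ = training_table
    return na.fit_gpr(
        table[list(na.FEATURE_COLUMNS)],
        table["age"],
        na.KernelConfig(n_restarts=0, seed=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
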