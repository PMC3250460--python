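import numpy as np
import pytest

from methex import SimulationConfig, generate_expression_cohort, generate_methylation_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_probes=300,
        n_genes=300,
        n_pairs_per_batch=(12, 12),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    beta, sheet, truth = generate_methylation_cohort(small_config)
    return beta, sheet, truth


@pytest.fixture(scope="session")
def small_expression(small_config, small_cohort):
    _, _, truth = small_cohort
    expr, sheet = generate_expression_cohort(small_config, truth)
    return expr, sheet


@pytest.fixture(scope="session")
def annotation(small_cohort):
    _, _, truth = small_cohort
    return truth.probes[["gene_id"]].reset_index()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
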