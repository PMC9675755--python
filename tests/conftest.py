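import numpy as np
import pytest

from enhancersens import pipeline
from enhancersens.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def ppre_pwm():
    return pipeline.default_ppre_pwm()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study for fast smoke tests (same structure, 40 targets)."""
    return SimulationConfig(
        chrom_count=2,
        chrom_length=650_000,
        enhancers_per_group=10,
        n_background_sites=20,
        linked_genes_per_group=5,
        n_pool_genes=220,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return pipeline.run_all(small_config, seed=7)


@pytest.fixture(scope="session")
def default_result():
    """The full default-scale synthetic study, shared across tests."""
    return pipeline.run_all(seed=1)
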