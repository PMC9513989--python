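import numpy as np
import pytest

from cloneflow.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_mutations_per_clone=50, depth_mean=300, n_cells=60)
    truth, records, single_cells, cnvs = simulate_cohort(cfg)
    return cfg, truth, records, single_cells, cnvs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
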