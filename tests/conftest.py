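import numpy as np
import pytest

from mrevo.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_samples=3, n_clones=4, n_trunk_snvs=20,
                           n_branch_snvs_per_clone=10, n_segments=22,
                           n_het_snps_per_segment=15, seed=42)
    truth, tables = simulate_cohort(cfg)
    return cfg, truth, tables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
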