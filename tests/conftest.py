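import numpy as np
import pytest

from tmm_scell import SimConfig, demo_tmm_collection, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-cell cohort with planted signal, shared across tests."""
    cfg = SimConfig(n_cells=300, n_genes=800, signature_lfc=1.5, seed=42)
    sets = demo_tmm_collection(cfg.n_genes)
    counts, truth = simulate_cohort(cfg, sets)
    return counts, truth, sets, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
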