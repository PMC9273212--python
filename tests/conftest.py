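import numpy as np
import pandas as pd
import pytest

from cfrnaflow.simulate import SimConfig, simulate_cohort, simulate_human_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort (2 groups x 12 samples)."""
    config = SimConfig(n_groups=2, n_per_group=12, n_genes=300, n_genera=50,
                       n_de_per_group=30, seed=11)
    human, samples, kmer, alignment, resources, truth = simulate_cohort(
        config, fail_fraction=0.25)
    return {"config": config, "human": human, "samples": samples,
            "kmer": kmer, "alignment": alignment, "resources": resources,
            "truth": truth}


@pytest.fixture(scope="session")
def binary_cohort():
    """Moderate two-group cohort for normalization/classification tests."""
    config = SimConfig(n_groups=2, n_per_group=25, n_genes=500,
                       n_de_per_group=40, seed=7)
    human, samples, truth = simulate_human_counts(config)
    return {"config": config, "human": human, "samples": samples,
            "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
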