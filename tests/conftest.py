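import numpy as np
import pandas as pd
import pytest

from braintx import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_probe_set():
    """2 donors x 10 regions x (50 genes x 3 probes), 20% planted below background."""
    return synthetic.gen_probe_samples(
        n_donors=2, n_regions=10, n_genes=50, probes_per_gene=3,
        background_rate=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def small_subjects():
    """60 + 60 subjects over 40 regions with default covariate effects."""
    gradient = pd.Series(
        np.random.default_rng(3).standard_normal(40), index=synthetic.region_ids(40)
    )
    gradient = (gradient - gradient.mean()) / gradient.std(ddof=0)
    return synthetic.gen_subjects(60, 60, gradient, seed=5)
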