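import numpy as np
import pytest

from tempomics import StudyConfig, simulate_null, unit_normalize
from tempomics.spectral import bootstrap_cutoffs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return StudyConfig(seed=1, n_boot=5000)


@pytest.fixture(scope="session")
def null_cutoffs_24():
    """Cutoffs calibrated on a clean unit-normalized null background (N=24)."""
    null = simulate_null(2000, 24, seed=100)
    pool = np.vstack([unit_normalize(r) for r in null.values])
    return bootstrap_cutoffs(pool.ravel(), 24, n_boot=50_000, p=0.01, seed=101)
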