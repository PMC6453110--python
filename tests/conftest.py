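import numpy as np
import pytest

import fovealbias as fb


@pytest.fixture(scope="session")
def fast_boot():
    """Bootstrap config small enough for unit tests, above the warning floor."""
    return fb.BootstrapConfig(n_samples=2000, seed=11)


@pytest.fixture(scope="session")
def exp1_trials():
    """One moderately sized simulated experiment-1 dataset (both sessions)."""
    return fb.simulate_cohort(1, 10, master_seed=42)


@pytest.fixture(scope="session")
def exp2_trials():
    return fb.simulate_cohort(2, 9, master_seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
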