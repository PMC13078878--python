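import numpy as np
import pytest

from dnbpipe import SyntheticParams, simulate_timecourse


@pytest.fixture(scope="session")
def small_params():
    """A fast, fully planted course: 300 genes, 20-gene module, strong bump."""
    return SyntheticParams(n_genes=300, module_size=20, seed=7)


@pytest.fixture(scope="session")
def small_course(small_params):
    tc, truth = simulate_timecourse(small_params)
    return tc, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
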