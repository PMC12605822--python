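import numpy as np
import pytest

from abnormap.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-site cohort shared across tests (128 regions)."""
    cfg = GeneratorConfig(n_controls=60, n_patients=40, n_regions=128, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
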