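import numpy as np
import pytest

from fastproteo import synthetic_data as sd


@pytest.fixture(scope="session")
def design():
    return sd.StudyDesign.default()


@pytest.fixture(scope="session")
def small_study():
    """One small seeded study shared across read-only tests."""
    cfg = sd.SimConfig(n_per_cluster=4, n_null=20, n_noise=4)
    return sd.generate_study(cfg, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
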