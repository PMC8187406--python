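import numpy as np
import pytest

from secretomap.syndata import SimConfig, generate_study


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """Noise-free study: every planted set must be recovered exactly."""
    cfg = SimConfig(n_genes=300, detection_dropout=0.0, lognormal_sigma=0.0,
                    plasma_sigma=0.0, seed=42)
    return generate_study(cfg, tmp_path_factory.mktemp("clean_study"))


@pytest.fixture(scope="session")
def noisy_study(tmp_path_factory):
    """Realistic study: dropout and abundance noise switched on."""
    cfg = SimConfig(n_genes=300, detection_dropout=0.15, lognormal_sigma=0.5,
                    seed=7)
    return generate_study(cfg, tmp_path_factory.mktemp("noisy_study"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
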