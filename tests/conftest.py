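import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ftirdose.bis import compute_bis
from ftirdose.preprocess import preprocess_collection
from ftirdose.spectra import SpectrumCollection, WavenumberGrid
from ftirdose.synth import GeneratorConfig, generate_design, generate_spectrum, noise_free

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_config() -> GeneratorConfig:
    return noise_free(GeneratorConfig())


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def noise_free_design(noise_free_config):
    """One replicate per dose, noise-free (replicates would be identical)."""
    cfg = noise_free(GeneratorConfig(n_replicates=1))
    return generate_design(cfg)


@pytest.fixture(scope="session")
def preprocessed_design(default_config):
    """The full noisy 9x7 design, preprocessed. Shared across tests."""
    return preprocess_collection(generate_design(default_config))


@pytest.fixture(scope="session")
def default_bis(preprocessed_design):
    return compute_bis(preprocessed_design)


@pytest.fixture
def small_grid() -> WavenumberGrid:
    return WavenumberGrid(np.array([1000.0, 1001.0, 1002.0, 1003.0, 1004.0]))


@pytest.fixture
def tiny_collection(small_grid):
    from ftirdose.spectra import Spectrum

    return SpectrumCollection([
        Spectrum(small_grid, np.array([0.1, 0.4, 0.9, 0.4, 0.1]), dose=0.0, replicate_id=1),
        Spectrum(small_grid, np.array([0.2, 0.5, 1.0, 0.5, 0.2]), dose=1.0, replicate_id=1),
    ])
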