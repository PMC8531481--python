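import numpy as np
import pytest

from sportfuse import GeneratorConfig, SpectrumSet, generate_dataset
from sportfuse.synthdata import noise_free


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced-scale generator: 5 classes, coarse grid, default artifacts."""
    return GeneratorConfig(n_per_class=12, wavenumber_step=16, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SpectrumSet:
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_dataset(small_config) -> SpectrumSet:
    """Same design without any scatter artifacts or noise."""
    return generate_dataset(noise_free(small_config))


def make_two_block_regression(seed: int = 0, n: int = 70, p: int = 20,
                              noise: float = 0.1):
    """Two blocks carrying complementary halves of the response signal."""
    rng = np.random.default_rng(seed)
    s1 = rng.normal(size=n)
    s2 = rng.normal(size=n)
    b1 = np.outer(s1, rng.normal(size=p)) + noise * rng.normal(size=(n, p))
    b2 = np.outer(s2, rng.normal(size=p)) + noise * rng.normal(size=(n, p))
    return b1, b2, s1 + s2
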