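import numpy as np
import pytest

from lensbench import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 + 30 synthetic lens images at full severity (shared across tests)."""
    return generate_dataset(
        GeneratorConfig(n_positive=30, n_negative=30, severity=1.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_gray_images(rng):
    """Ten random 8x8 8-bit gray images for oracle-equivalence checks."""
    return [rng.integers(0, 256, size=(8, 8)).astype(np.uint8) for _ in range(10)]
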