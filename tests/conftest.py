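import numpy as np
import pytest

from faersig.synthetic import SyntheticConfig, generate, generate_event_table


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A 2,000-case default-structure bundle: fast, every feature present."""
    return SyntheticConfig(n_cases=2000, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_events(small_config):
    return generate_event_table(small_config)


def random_tables(seed: int, n: int, low: int = 1, high: int = 400) -> np.ndarray:
    """n random strictly-positive fourfold tables as an (n, 4) array."""
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=(n, 4))
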