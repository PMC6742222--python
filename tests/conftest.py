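import numpy as np
import pandas as pd
import pytest

from dkhei import GeneratorConfig, simulate_pairs


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 4,000-pair synthetic cohort shared across tests (fixed seed)."""
    cohort, _ = simulate_pairs(GeneratorConfig(n_pairs=4000), seed=42)
    return cohort


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
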