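import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from twingxe.scenarios import clean_params
from twingxe.synthetic_registry import generate_registry


@pytest.fixture(scope="session")
def small_registry() -> pd.DataFrame:
    """A confound-free 2k-pair registry for structural tests."""
    return generate_registry(clean_params(n_pairs=2_000, p_mz=0.3), seed=11)


@pytest.fixture(scope="session")
def full_registry() -> pd.DataFrame:
    """A 5k-pair registry under the default study conditions (all
    confounds on)."""
    from twingxe.synthetic_registry import GenerativeParams

    return generate_registry(GenerativeParams(n_pairs=5_000, seed=7), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
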