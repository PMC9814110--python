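import numpy as np
import pandas as pd
import pytest

from sensipod import SyntheticSpec, generate_training_table


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(n_chemicals=80, seed=7)


@pytest.fixture(scope="session")
def training_table(default_spec) -> pd.DataFrame:
    return generate_training_table(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
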