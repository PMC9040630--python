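import numpy as np
import pandas as pd
import pytest

from ogukit.synthgen import make_conceptual_fixture
from ogukit.tables import FeatureTable


@pytest.fixture(scope="session")
def concept_fixture():
    return make_conceptual_fixture()


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {"S1": [5.0, 3.0, 0.0], "S2": [0.0, 2.0, 7.0]},
        index=["G1", "G2", "G3"],
    )
    return FeatureTable(df, "rounded_int")


def random_int_table(rng: np.random.Generator, n_features=8, n_samples=4, high=50):
    data = rng.integers(0, high, size=(n_features, n_samples)).astype(float)
    df = pd.DataFrame(
        data,
        index=[f"G{i}" for i in range(n_features)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return FeatureTable(df, "rounded_int")
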