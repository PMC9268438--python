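import numpy as np
import pytest

from ginsengms import SyntheticSpec, generate_feature_table
from ginsengms.multivariate import normalize_zscore


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def strong_signal_table():
    """Well-separated three-class table (no missingness) plus truth."""
    table, truth = generate_feature_table(
        SyntheticSpec(seed=1, effect_size=3.0, missing_prob=0.0)
    )
    return table, truth


@pytest.fixture(scope="session")
def strong_signal_zscores(strong_signal_table):
    table, truth = strong_signal_table
    return normalize_zscore(table).values, list(table.origins), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
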