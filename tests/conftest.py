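import numpy as np
import pytest

from epiloop.gbm import GbmParams, fit_gbm
from epiloop.synthetic import SyntheticConfig, generate_promoter_table


@pytest.fixture(scope="session")
def default_table():
    """The default synthetic promoter table (n=2000, seed 1)."""
    return generate_promoter_table(SyntheticConfig(seed=1, n_promoters=2000))


@pytest.fixture(scope="session")
def small_forest(default_table):
    """A light 50-tree ensemble on the default table, for SHAP tests."""
    params = GbmParams.desk(seed=1, n_estimators=50)
    return fit_gbm(default_table.X(), default_table.y(), params,
                   feature_names=default_table.feature_names)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tiny_params(**kw):
    kw.setdefault("n_estimators", 20)
    kw.setdefault("min_data_per_leaf", 1)
    kw.setdefault("max_leaves", 8)
    kw.setdefault("n_folds", 2)
    return GbmParams(**kw)
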