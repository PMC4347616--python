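import numpy as np
import pytest

from grainforest import GrainTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """8 examples, 2 features, 4 grain values of 2 examples each, class-pure."""
    rng = np.random.default_rng(7)
    features = rng.random((8, 2))
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    grain_ids = np.array(["gA", "gA", "gB", "gB", "gC", "gC", "gD", "gD"])
    return GrainTable(features, labels, grain_ids, ["x1", "x2"])


@pytest.fixture
def separable_table():
    """Perfectly separable one-feature table with many singleton grains."""
    rng = np.random.default_rng(11)
    n = 60
    labels = np.repeat([0, 1], n // 2)
    x = np.where(labels == 1, 1.0, 0.0) + rng.normal(0, 0.01, n)
    return GrainTable(x.reshape(-1, 1), labels, np.arange(n).astype(str), ["x"])
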