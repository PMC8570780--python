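import numpy as np
import pytest

from passforge import (
    UniverseConfig,
    build_universe,
    train_teacher,
)


@pytest.fixture(scope="session")
def universe():
    """One default-config universe shared across the suite (seed 7)."""
    return build_universe(UniverseConfig(seed=7))


@pytest.fixture(scope="session")
def teacher(universe):
    truth = {e.family: e.labels for e in universe.labelled_train}
    pairs = [(c, truth[c.family]) for c in universe.labelled_train_clusters]
    return train_teacher(pairs, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
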