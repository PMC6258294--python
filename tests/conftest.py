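import numpy as np
import pytest

import xenomir as x


@pytest.fixture(scope="session")
def table1_dataset():
    """The default planted-effect study dataset at full class sizes."""
    cfg = x.table1_like_config(seed=1)
    dataset, pool, truth = x.generate_dataset(cfg)
    return cfg, dataset, pool, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down planted-effect dataset for fast model tests."""
    cfg = x.table1_like_config(seed=3, n_pos=60, n_neg=150, n_unlabeled=80)
    dataset, pool, truth = x.generate_dataset(cfg)
    return cfg, dataset, pool, truth


def labels_of(records):
    return np.array([1 if r.label == "positive" else 0 for r in records])
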