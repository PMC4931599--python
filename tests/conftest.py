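import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import twinmeth as tm


@pytest.fixture(scope="session")
def small_cohort():
    """Three-region cohort, 80 features, mild effects, planted signal."""
    cfg = tm.gse37579_like_config(
        5,
        n_features=80,
        n_signal_features=8,
        signal_effect=1.5,
        batch_additive_sd=0.8,
        strat_sd=1.0,
        pair_sd=0.5,
        pairs_per_batch=(6, 8, 10),
        batch_labels=("A", "B", "C"),
    )
    return tm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_regions(small_cohort):
    data, _ = small_cohort
    return data.split_by_batch()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
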