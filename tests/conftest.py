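import numpy as np
import pytest

from tritarget.de import run_de
from tritarget.simulate import (
    SimTruth,
    assign_repeat_labels,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_truth():
    return SimTruth(seed=0)


@pytest.fixture(scope="session")
def default_labels(default_truth):
    return assign_repeat_labels(default_truth)


@pytest.fixture(scope="session")
def small_cohort(default_truth, default_labels):
    """A 20v10 cohort at default planted conditions, DE already run."""
    sim = simulate_counts(default_truth, default_labels, n_case=20, n_control=10)
    filtered, nm, det = run_de(sim.counts, fc_threshold=1.0)
    return sim, nm, det


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
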