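import numpy as np
import pytest

from statefield.synthetic import make_ground_truth, make_neuron_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_gt():
    """A coupled ground-truth neuron at fast-test scale."""
    return make_ground_truth(11, grid=12, kernel=7, coupling_gain=0.6,
                             target_rate_hz=30.0, n_lfp_channels=3)


@pytest.fixture(scope="session")
def small_dataset(small_gt):
    """Reduced-scale dataset: 2 training ensembles, 6 repeats."""
    return make_neuron_dataset(small_gt, seed=5, n_train_ensembles=2,
                               n_reps=6)
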