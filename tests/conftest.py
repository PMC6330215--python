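import numpy as np
import pytest

from dynsubgraphs.networks import concatenate
from dynsubgraphs.synthetic import (make_ground_truth, make_partition,
                                    render_connectivity)


@pytest.fixture(scope="session")
def partition40():
    return make_partition(40, 4)


@pytest.fixture(scope="session")
def planted_cohort(partition40):
    """Desk-scale planted cohort shared across tests: 40 regions,
    4 systems, k_true=4, T=51, S=40."""
    gt = make_ground_truth(40, 4, partition40, n_windows=51, n_subjects=40,
                           seed=11)
    X0 = concatenate(render_connectivity(gt, 0.0))
    Xn = concatenate(render_connectivity(gt, 0.05))
    return {"gt": gt, "X_clean": X0, "X_noisy": Xn}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
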