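import numpy as np
import pytest

import torsmap as tm

#: barrier heights (k_B*T) of the six sildenafil torsions and the rounded
#: weights they normalize to
TABLE1_BARRIERS = [6.0, 1.5, 2.0, 1.2, 2.5, 4.0]
TABLE1_WEIGHTS = [5.0, 1.3, 1.7, 1.0, 2.1, 3.3]


@pytest.fixture(scope="session")
def table1_weights():
    return tm.compute_weights(TABLE1_BARRIERS,
                              angle_names=list("ABCDEF"))


@pytest.fixture(scope="session")
def world():
    """Default 12-conformer, 6-torsion planted world."""
    return tm.sildenafil_like_world()


@pytest.fixture(scope="session")
def reference_run(world, table1_weights):
    """One clustered synthetic reference trajectory shared across tests."""
    traj, truth = tm.sample_unbiased(world, 6000, seed=1)
    model = tm.DensityPeaks(weights=table1_weights,
                            store_dtype="float32").fit(traj.angles)
    return traj, truth, model


@pytest.fixture
def rng():
    return np.random.default_rng(42)
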