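import numpy as np
import pytest

import acuglm as a
from acuglm.kernels import make_kernels


@pytest.fixture(scope="session")
def kernels():
    """Default kernels at 1 ms bins."""
    return a.default_kernels()


@pytest.fixture(scope="session")
def tiny_kernels():
    """Short-support kernels for hand-checkable toy problems."""
    return make_kernels(
        stim_amp=1.0,
        stim_tau=0.003,
        dep_depth=0.0,
        dep_recovery=0.002,
        stim_support=0.006,
        hist_amp=1.0,
        hist_tau=0.002,
        hist_refract_tau=0.001,
        hist_support=0.005,
        hist_balance=1.0,
    )


@pytest.fixture(scope="session")
def toy_problem(tiny_kernels):
    """A 20-bin, 3-neuron toy: stimulus, hand-set spike counts, design matrix."""
    dt = 1e-3
    stim = a.make_stimulus_train(60 * 1000 / 6, 0.020, dt, tiny_kernels)  # event every 6 bins
    counts = np.zeros((3, 20), dtype=np.int64)
    counts[0, [2, 9, 15]] = 1
    counts[1, [4, 9]] = 1
    counts[2, [7]] = 2
    spikes = a.SpikeTrainSet(grid=stim.grid, counts=counts)
    design = a.build_design(stim, spikes, tiny_kernels)
    return stim, spikes, design


@pytest.fixture(scope="session")
def reference_params():
    return a.reference_true_params()
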