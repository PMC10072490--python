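import numpy as np
import pytest

from mitopart import SweepSpec, run_sweep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def symmetric_grid_sweep():
    """Full 11x11 (p, q) inclusion grid at symmetric division.

    s = 4 (heterogeneous networks), h = 0.5, N0 = 100, 2000 replicates per
    cell, random placement, no diffusion.  Shared across the pattern tests
    that read different aspects of the same experiment.
    """
    spec = SweepSpec(
        seeds_list=[4],
        h_list=[0.5],
        N0_list=[100],
        reps=2000,
        master_seed=11,
    )
    return run_sweep(spec)
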