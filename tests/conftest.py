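import numpy as np
import pytest

from hootube.chimp_tract import ParamGrid, TractParams, run_sweep


@pytest.fixture(scope="session")
def full_sweep():
    """The complete default-grid sweep (8550 configurations), run once."""
    return run_sweep(ParamGrid())


@pytest.fixture(scope="session")
def small_sweep():
    """A cheap 12-configuration sweep for interface-level tests."""
    grid = ParamGrid(
        protrusion_lengths=(0.2, 2.0),
        sac_lengths=(1.0,),
        sac_areas=(1.0, 10.0, 30.0),
        lip_opening_areas=(0.2, 1.0),
    )
    return run_sweep(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
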