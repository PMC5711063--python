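import numpy as np
import pytest

import respcomp as rc
from respcomp.experiment import load_config, paper_profile_path, run_experiment

#: measured standstill 95% isodose area the beam is calibrated against, cm^2
STANDSTILL_AREA95 = 5.36


@pytest.fixture(scope="session")
def beam():
    """Beam with the penumbra calibrated to the standstill 95% area."""
    return rc.calibrate_penumbra(STANDSTILL_AREA95, rc.BeamModel())


@pytest.fixture(scope="session")
def grid_spec():
    return rc.GridSpec()


@pytest.fixture(scope="session")
def standstill(beam, grid_spec):
    return rc.accumulate(beam, None, 44.4, grid_spec)


@pytest.fixture(scope="session")
def paper_run():
    """The full seven-group sine experiment from the shipped profile."""
    return run_experiment(load_config(paper_profile_path()))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
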