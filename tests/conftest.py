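import numpy as np
import pytest

from sacsim import (SolverSettings, build_full_network,
                    reference_parameters, simulate)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def full_net(ref_params):
    return build_full_network(ref_params)


@pytest.fixture(scope="session")
def wt_timecourse(full_net):
    """Deterministic wild-type trajectory covering attachment + exit."""
    return simulate(full_net, SolverSettings(mode="deterministic",
                                             t_end=6000.0, n_out=1200))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
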