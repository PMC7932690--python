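import warnings

import numpy as np
import pytest

import choxamp as cx


@pytest.fixture(scope="session")
def kinetics():
    return cx.KineticConstants()


@pytest.fixture(scope="session")
def grid():
    return cx.GridSpec()


@pytest.fixture(scope="session")
def coating():
    return cx.CoatingSpec(thickness=30.0, e0=263.0)


@pytest.fixture(scope="session")
def short_staircase(kinetics, grid, coating):
    """Shared two-step O2 staircase with profile snapshots (settled plateaus)."""
    proto = cx.BulkProtocol.standard_calibration(hold=20.0, pre_hold=60.0,
                                                 o2_max=10.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trace = cx.run_protocol(proto, coating, grid, kinetics,
                                keep_snapshots=True)
    return proto, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
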