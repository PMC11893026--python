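"""Shared fixtures: small, fast scheme/simulation setups reused across tests."""

import numpy as np
import pytest

from cvpgrad import (GradientChainModel, SliceSet, build_scheme,
                     choose_prephasers, make_slice_select, make_trapezoid,
                     simulate_fid)


@pytest.fixture(scope="session")
def trapezoid_test():
    return make_trapezoid(10.0, 150.0, 300.0, 1.0)


@pytest.fixture(scope="session")
def slice_select():
    return make_slice_select(6.0, 100.0, 300.0, 1.0)


@pytest.fixture(scope="session")
def slices9():
    return SliceSet(np.linspace(-20.0, 20.0, 9), 3.0)


@pytest.fixture(scope="session")
def ideal_model():
    """Band-limited but otherwise clean chain (no eddy/resonance terms)."""
    return GradientChainModel(delay=2.0, lowpass_bandwidth=15.0)


@pytest.fixture(scope="session")
def cvp_scheme(trapezoid_test, slice_select):
    ss, exc = slice_select
    amps = choose_prephasers(trapezoid_test, 5)
    return build_scheme("cvp", trapezoid_test, amps, ss, exc,
                        readout_duration=1500.0)


@pytest.fixture(scope="session")
def cvp_data_ideal(cvp_scheme, ideal_model, slices9):
    """Noiseless CVP acquisition of the trapezoid through the clean chain."""
    return simulate_fid(cvp_scheme, ideal_model, slices9, dwell=2.0)
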