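import numpy as np
import pytest

import qamskit as qk


@pytest.fixture(scope="session")
def response():
    return qk.ResponseModel()


@pytest.fixture(scope="session")
def profile():
    return qk.InstrumentProfile()


@pytest.fixture(scope="session")
def noiseless_profile():
    return qk.InstrumentProfile().noiseless()


@pytest.fixture(scope="session")
def library():
    return qk.RRTLibrary.default()


@pytest.fixture(scope="session")
def batch_tables():
    return qk.load_fixture("batch_contents")


@pytest.fixture(scope="session")
def noiseless_series(response, noiseless_profile):
    """Processed six-level mixed-standard series, no noise."""
    return qk.standard_series_tables(response=response, profile=noiseless_profile)


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_series):
    return qk.curves_from_series(noiseless_series)


@pytest.fixture(scope="session")
def noiseless_rcfs(noiseless_series):
    return qk.rcfs_from_series(noiseless_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240409)
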