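import numpy as np
import pytest

from vdamri.phantom.geometry import build_phantom, parameter_volumes
from vdamri.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_phantom():
    """A small pre-treatment phantom shared by read-only tests."""
    labels, records = build_phantom((32, 32, 10), "pre", seed=0)
    return labels, records, parameter_volumes(labels, records)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
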