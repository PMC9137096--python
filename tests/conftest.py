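import warnings

import pytest

from orgstack import OpticalModel, StainingModel, plan_zstack


@pytest.fixture(autouse=True)
def _quiet_plane_warnings():
    # plans whose rounded step overshoots the gel top warn by design
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="acquisition planes extend outside the gel depth")
        yield


@pytest.fixture
def optics():
    return OpticalModel()


@pytest.fixture
def plan7():
    """The reference scan: 7 layers over an 1100 um gel (180 um step)."""
    return plan_zstack(1100.0, 7)


@pytest.fixture
def quenched_staining():
    return StainingModel(cu_concentration=0.1)
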