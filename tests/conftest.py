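import pytest

from adpkdsim import calibrate


@pytest.fixture(scope="session")
def fitted():
    """Parameters calibrated once to the base-case anchors."""
    return calibrate()
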