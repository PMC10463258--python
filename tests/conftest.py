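import pytest

from splicefrac import TraceParams, default_reference_pair


@pytest.fixture
def refs():
    """Default serine-junction reference pair (3-nt insert)."""
    return default_reference_pair()


@pytest.fixture
def noiseless():
    """Trace forward-model parameters with noise switched off."""
    return TraceParams(noise_sd=0.0)
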