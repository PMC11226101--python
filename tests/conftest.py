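import pytest

from spikevt import LIFParameters, SynapseModel, TimeConstantModel, make_stream


@pytest.fixture
def lif_params():
    """Standard electrophysiological constants: asymptote -53 mV, threshold
    -55 mV, 1000 steps of 1 ms."""
    return LIFParameters()


@pytest.fixture
def exp_tc():
    """Shifted-exponential time-constant law, mu=20 ms, e-folding scale 5 ms."""
    return TimeConstantModel("exponential", mu=20.0, sigma=5.0, convention="scale")


@pytest.fixture
def pareto_tc():
    """Pareto time-constant law, mu=20 ms, tail index 20."""
    return TimeConstantModel("pareto", mu=20.0, sigma=20.0)


@pytest.fixture
def stream():
    return make_stream(12345)


@pytest.fixture
def synapse():
    return SynapseModel()
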