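import pytest

from hfovbench.circuit_core import GasConditions
from hfovbench.synthetic_bench import NoiseParams, SimConfig


@pytest.fixture
def gas():
    return GasConditions()


@pytest.fixture
def noiseless_config():
    """Default bench condition with all noise sources and capnometer lag off."""
    return SimConfig(
        noise=NoiseParams(flow_sd=0.0, pco2_sd=0.0),
        capno_time_constant=0.0,
    )
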