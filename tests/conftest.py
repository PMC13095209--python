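import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_net():
    """The four-neuron demonstration network (A..D, seven directed edges)."""
    from wormnet.synthetic import worked_example

    return worked_example()
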