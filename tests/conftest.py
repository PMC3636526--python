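import pytest

from proforms.synthetic import spindle_fixture


@pytest.fixture(scope="session")
def fx():
    """The deterministic spindle-checkpoint fixture (built once)."""
    return spindle_fixture()


@pytest.fixture(scope="session")
def graph(fx):
    return fx.graph()
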