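import pytest

from modrhod import synthetic


@pytest.fixture(scope="session")
def br_scaffold():
    return synthetic.make_scaffold("BR", seed=0)


@pytest.fixture(scope="session")
def chr2_scaffold():
    return synthetic.make_scaffold("ChR2", seed=1)
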