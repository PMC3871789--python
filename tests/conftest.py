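import pytest

from dtlrec import EventCosts


@pytest.fixture
def hogenom():
    return EventCosts(dup=3.5, trans=3.0, loss=1.0)


@pytest.fixture
def unit_costs():
    return EventCosts(dup=1.0, trans=1.0, loss=1.0)
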