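import pytest

from dsdlogic import paper_gate


@pytest.fixture(scope="session")
def or_gate():
    return paper_gate("OR")


@pytest.fixture(scope="session")
def and_gate():
    return paper_gate("AND")


@pytest.fixture(scope="session")
def majority_gate():
    return paper_gate("MAJORITY")


@pytest.fixture(scope="session", params=["OR", "AND", "MAJORITY"])
def any_gate(request):
    return paper_gate(request.param)


def input_subset(gate, state):
    """Input strands present in a bit-triple state."""
    return [inp for inp, bit in zip(gate.inputs, state) if bit]
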