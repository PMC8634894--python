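import pytest

from actnet import fixtures
from actnet.model import EdgeSpec, NetworkModel, NodeSpec


@pytest.fixture
def ras_motif():
    return fixtures.motif("ras_motif")


@pytest.fixture
def abc_example():
    return fixtures.motif("abc_example")


@pytest.fixture
def mini_chondro():
    return fixtures.motif("mini_chondro")


@pytest.fixture
def mini_classifier():
    return fixtures.motif_classifier("mini_chondro")


@pytest.fixture
def delayed_switch():
    return fixtures.motif("delayed_switch")


@pytest.fixture
def destruction_complex():
    return fixtures.motif("destruction_complex")


@pytest.fixture
def single_decay():
    """One node with only a self-inhibition loop."""
    return NetworkModel(
        nodes=[NodeSpec("A", initial=100)],
        edges=[EdgeSpec(("A",), "A", "inhibition", 1, 1.0)],
    )


X_PLUS_INIT = {"X": 100, "XA": 100, "M1": 100, "XW": 100}


@pytest.fixture
def x_plus_levels(mini_chondro):
    """Reported levels of mini_chondro's X+ attractor."""
    from actnet.simulate import find_attractor

    att = find_attractor(mini_chondro, init=X_PLUS_INIT)
    assert att.kind == "fixed_point"
    return att.reported_levels
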