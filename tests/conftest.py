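import numpy as np
import pytest

from netnegsel.network import WeightedNetwork


def make_net(w: np.ndarray, labels=None) -> WeightedNetwork:
    """Wrap a matrix directly as a normalized network (test convenience)."""
    w = np.asarray(w, dtype=float)
    labels = labels or [f"n{i}" for i in range(len(w))]
    return WeightedNetwork(node_labels=list(labels), w=w, degree=w.sum(axis=1))


@pytest.fixture
def path_abc() -> WeightedNetwork:
    """Path a-b-c with weights 0.4 and 0.6 (the worked micro-example)."""
    w = np.array([[0, 0.4, 0], [0.4, 0, 0.6], [0, 0.6, 0]])
    return make_net(w, labels=["a", "b", "c"])


@pytest.fixture
def star4() -> WeightedNetwork:
    """Star with center index 0 and three leaves, unit weights."""
    w = np.zeros((4, 4))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return make_net(w, labels=["c", "l1", "l2", "l3"])


@pytest.fixture
def triangle() -> WeightedNetwork:
    w = np.full((3, 3), 0.5)
    np.fill_diagonal(w, 0.0)
    return make_net(w)


@pytest.fixture(scope="session")
def tiny_dataset():
    from netnegsel.synthetic import make_fixture

    return make_fixture("tiny")
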