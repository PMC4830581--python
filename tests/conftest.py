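import numpy as np
import pytest

from hanoiplan import GraphArrays, PriorModel, build_graph


@pytest.fixture(scope="session")
def graph():
    return build_graph()


@pytest.fixture(scope="session")
def model(graph):
    return PriorModel.compute(graph)


@pytest.fixture(scope="session")
def arrays(graph):
    return GraphArrays(graph)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
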