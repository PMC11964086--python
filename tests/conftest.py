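import numpy as np
import pytest

from patchchaos import default_chip_layout
from patchchaos.chip_topology import ChipGraph


@pytest.fixture(scope="session")
def chip():
    return default_chip_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_path_graph(n: int) -> ChipGraph:
    ids = tuple(range(1, n + 1))
    edges = frozenset((i, i + 1) for i in range(1, n))
    coords = {i: (float(i), 0.0) for i in ids}
    return ChipGraph(ids, edges, coords)


def make_cycle_graph(n: int) -> ChipGraph:
    ids = tuple(range(1, n + 1))
    edges = {(i, i + 1) for i in range(1, n)} | {(1, n)}
    coords = {i: (np.cos(2 * np.pi * i / n), np.sin(2 * np.pi * i / n)) for i in ids}
    return ChipGraph(ids, frozenset(edges), coords)


@pytest.fixture()
def path4():
    return make_path_graph(4)


def logistic_series(n: int = 500, x0: float = 0.4, r: float = 4.0) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for t in range(n - 1):
        x[t + 1] = r * x[t] * (1.0 - x[t])
    return x


@pytest.fixture()
def logistic():
    return logistic_series()
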