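import numpy as np
import pytest

from causalmi import DataTable
from causalmi.benchmarks import _monotone_cpt
from causalmi.simulation import BayesNet, forward_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, columns=None):
    """DataTable from an int array, levels inferred per column."""
    values = np.asarray(values)
    p = values.shape[1]
    columns = columns or [f"X{j}" for j in range(p)]
    levels = [[str(i) for i in range(int(values[:, j].max()) + 1)]
              for j in range(p)]
    return DataTable(values, columns, levels)


def binary_bn(parents: dict, strength: float = 1.6) -> BayesNet:
    """Binary Bayes net with logistic-in-parent-spins CPTs."""
    nodes = list(parents)
    cpts = {v: _monotone_cpt(len(parents[v]), strength) for v in nodes}
    return BayesNet(nodes, parents, {v: 2 for v in nodes}, cpts)


@pytest.fixture
def chain_data():
    """10,000 samples from the chain A -> B -> C."""
    bn = binary_bn({"A": [], "B": ["A"], "C": ["B"]})
    return forward_sample(bn, 10000, seed=42), bn


@pytest.fixture
def collider_data():
    """10,000 samples from the collider A -> C <- B."""
    bn = binary_bn({"A": [], "B": [], "C": ["A", "B"]})
    return forward_sample(bn, 10000, seed=43), bn
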