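import numpy as np
import pytest
from hypothesis import settings

from netcontrol import ControlProblem, DirectedNetwork

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def chain():
    """a -> b -> c."""
    return DirectedNetwork(arcs=[("a", "b"), ("b", "c")])


@pytest.fixture
def chain_problem(chain):
    return ControlProblem(network=chain, targets=("b", "c"))


@pytest.fixture
def hub():
    """h -> t1, h -> t2: one hub driving two equal-distance targets."""
    return DirectedNetwork(arcs=[("h", "t1"), ("h", "t2")])


@pytest.fixture
def hub_problem(hub):
    return ControlProblem(network=hub, targets=("t1", "t2"))


@pytest.fixture
def long_chain():
    """x0 -> x1 -> ... -> x9."""
    nodes = [f"x{i}" for i in range(10)]
    return DirectedNetwork(arcs=[(nodes[i], nodes[i + 1]) for i in range(9)])


def make_random_instance(seed, n_lo=8, n_hi=12, p=0.25, max_targets=4):
    """A seeded small random instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    net_rng = int(rng.integers(0, 2**31 - 1))
    import netcontrol as nc

    net = nc.gen_erdos_renyi(n, p=p, seed=net_rng)
    eligible = [v for v in net.nodes if net.graph.in_degree(v) >= 1]
    if len(eligible) < 2:
        return None
    k = int(rng.integers(2, min(max_targets, len(eligible)) + 1))
    idx = rng.choice(len(eligible), size=k, replace=False)
    targets = tuple(eligible[i] for i in sorted(idx))
    return ControlProblem(network=net, targets=targets)
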