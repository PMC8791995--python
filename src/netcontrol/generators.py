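"""Seeded benchmark network generators and perturbations.

Three directed families are provided, matching the usual benchmark
constructions: Erdős–Rényi G(n, p), directed scale-free preferential
attachment, and a Watts–Strogatz small-world ring converted to a digraph by
replacing each undirected edge with two opposite arcs (so its arc count is
exactly nominal_n * k for every seed and rewiring probability). Isolated
nodes are removed after generation; target counts are nevertheless taken as
a fraction of the *nominal* (pre-removal) node count.
"""
from __future__ import annotations

import networkx as nx
import numpy as np

from .network import DirectedNetwork, remove_isolated

__all__ = [
    "gen_erdos_renyi",
    "gen_small_world",
    "gen_scale_free",
    "pick_targets",
    "perturb_edges",
    "mark_preferred",
]


def _label(i: int) -> str:
    return f"n{i}"


def _from_nx(g: nx.DiGraph, nominal_n: int) -> DirectedNetwork:
    nodes = [_label(i) for i in range(nominal_n)]
    arcs = [(_label(u), _label(v)) for u, v in g.edges()]
    return remove_isolated(DirectedNetwork(nodes=nodes, arcs=arcs))


def gen_erdos_renyi(nominal_n: int, p: float = 0.005, seed: int = 0) -> DirectedNetwork:
    """Directed G(n, p): each ordered pair (u, v), u != v, gets an arc
    independently with probability p. Isolated nodes removed."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    g = nx.fast_gnp_random_graph(nominal_n, p, seed=seed, directed=True)
    return _from_nx(g, nominal_n)


def gen_small_world(
    nominal_n: int, k: int = 4, rewire_p: float = 0.2, seed: int = 0
) -> DirectedNetwork:
    """Watts–Strogatz ring (k nearest neighbors, rewiring probability
    ``rewire_p``) with every undirected edge replaced by two opposite arcs.

    Rewiring preserves the edge count, so the result always has exactly
    nominal_n * k arcs.
    """
    if k % 2 != 0 or k >= nominal_n:
        raise ValueError("k must be even and < nominal_n")
    if not 0.0 <= rewire_p <= 1.0:
        raise ValueError("rewire_p must be in [0, 1]")
    g = nx.watts_strogatz_graph(nominal_n, k, rewire_p, seed=seed).to_directed()
    return _from_nx(g, nominal_n)


def gen_scale_free(
    nominal_n: int,
    alpha: float = 0.41,
    beta: float = 0.54,
    gamma: float = 0.05,
    delta_in: float = 0.2,
    delta_out: float = 0.0,
    seed: int = 0,
) -> DirectedNetwork:
    """Directed preferential-attachment growth (Bollobás et al. model).

    Parallel arcs are collapsed to a simple digraph (self-loops kept);
    isolated nodes removed.
    """
    if abs(alpha + beta + gamma - 1.0) > 1e-9:
        raise ValueError("alpha + beta + gamma must equal 1")
    g = nx.scale_free_graph(
        nominal_n,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        delta_in=delta_in,
        delta_out=delta_out,
        seed=seed,
    )
    # MultiDiGraph -> simple digraph; DirectedNetwork collapses duplicates too
    return _from_nx(nx.DiGraph(g), g.number_of_nodes())


def pick_targets(
    net: DirectedNetwork, nominal_n: int, fraction: float = 0.05, seed: int = 0
) -> list[str]:
    """Sample round(fraction * nominal_n) distinct nodes with in-degree >= 1.

    The count is based on the nominal node count before isolated-node
    removal. Only nodes with positive in-degree are eligible (they have a
    chance to be controlled by an upstream input).
    """
    count = round(fraction * nominal_n)
    eligible = [v for v in net.nodes if net.graph.in_degree(v) >= 1]
    if count > len(eligible):
        raise ValueError(
            f"requested {count} targets but only {len(eligible)} nodes have in-degree >= 1"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=count, replace=False)
    return [eligible[i] for i in sorted(idx)]


def perturb_edges(
    net: DirectedNetwork, fraction: float = 0.05, seed: int = 0
) -> DirectedNetwork:
    """Remove a uniformly random floor(fraction * |arcs|) subset of arcs,
    keeping all nodes (even if isolated afterwards). Emulates false-positive
    interactions in the data."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_remove = int(fraction * net.n_arcs)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(net.n_arcs, size=n_remove, replace=False)) if n_remove else set()
    arcs = [a for i, a in enumerate(net.arcs) if i not in drop]
    return DirectedNetwork(nodes=net.nodes, arcs=arcs)


def mark_preferred(
    net: DirectedNetwork, fraction: float = 0.2, seed: int = 0
) -> frozenset[str]:
    """Synthetic preferred-node labelling for random benchmark networks.

    Random networks carry no intrinsic preferred set; this helper marks a
    random fraction of nodes preferred so the preference machinery can be
    exercised on synthetic data.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    count = round(fraction * net.n_nodes)
    rng = np.random.default_rng(seed)
    idx = rng.choice(net.n_nodes, size=count, replace=False)
    nodes = net.nodes
    return frozenset(nodes[i] for i in idx)
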