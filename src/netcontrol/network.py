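"""Directed-network data model, ancestor queries, and plain-text I/O.

Networks are simple directed graphs (parallel arcs collapsed, self-loops
permitted). Node order is the order of first appearance in the input and is
stable: it fixes matrix row/column indices and the arc ordering used to key
per-arc random weight streams, so that every downstream computation is
reproducible for a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "ControlProblem",
    "NetworkFormatError",
    "UnknownNodeError",
    "read_edge_list",
    "write_edge_list",
    "read_node_set",
    "adjacency_matrix",
    "ancestors_within",
    "remove_isolated",
]


class NetworkFormatError(ValueError):
    """Malformed edge-list or node-set input."""


class UnknownNodeError(KeyError):
    """A node id referenced in the input is not part of the network."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class DirectedNetwork:
    """A simple directed graph with a stable node order.

    Parameters
    ----------
    nodes
        Initial node ids, in order. Arc endpoints not listed here are
        appended in order of first appearance.
    arcs
        Iterable of ``(source, target)`` pairs. Duplicates are collapsed.
    """

    __slots__ = ("_graph", "_index", "_arcs")

    def __init__(self, nodes: Iterable[str] = (), arcs: Iterable[tuple[str, str]] = ()):
        g = nx.DiGraph()
        order: dict[str, int] = {}
        for node in nodes:
            node = str(node)
            if node not in order:
                order[node] = len(order)
                g.add_node(node)
        arc_list: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        n_dup = 0
        for u, v in arcs:
            u, v = str(u), str(v)
            if (u, v) in seen:
                n_dup += 1
                continue
            seen.add((u, v))
            for w in (u, v):
                if w not in order:
                    order[w] = len(order)
                    g.add_node(w)
            g.add_edge(u, v)
            arc_list.append((u, v))
        if n_dup:
            logger.info("collapsed %d duplicate arc(s)", n_dup)
        self._graph = g
        self._index = order
        self._arcs = tuple(arc_list)

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._index)

    @property
    def arcs(self) -> tuple[tuple[str, str], ...]:
        """Arcs in insertion order (the canonical arc indexing)."""
        return self._arcs

    @property
    def n_nodes(self) -> int:
        return len(self._index)

    @property
    def n_arcs(self) -> int:
        return len(self._arcs)

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying networkx digraph (treat as read-only)."""
        return self._graph

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise UnknownNodeError(f"unknown node id: {node!r}") from None

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self._arcs) == set(other._arcs)

    def __hash__(self):  # mutable-free but order-sensitive; rarely needed
        return hash((self.nodes, frozenset(self._arcs)))

    def __repr__(self) -> str:
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"

    # -- queries -----------------------------------------------------------

    def predecessors(self, node: str) -> list[str]:
        if node not in self._index:
            raise UnknownNodeError(f"unknown node id: {node!r}")
        return list(self._graph.predecessors(node))

    def successors(self, node: str) -> list[str]:
        if node not in self._index:
            raise UnknownNodeError(f"unknown node id: {node!r}")
        return list(self._graph.successors(node))

    def adjacency_matrix(self) -> np.ndarray:
        return adjacency_matrix(self)

    def ancestors_within(self, node: str, distance: int) -> set[str]:
        return ancestors_within(self, node, distance)


def adjacency_matrix(net: DirectedNetwork) -> np.ndarray:
    """0/1 adjacency with columns indexing sources: ``A[v, u] = 1`` iff arc
    ``(u, v)`` exists, so ``A @ x`` propagates along arc direction."""
    n = net.n_nodes
    a = np.zeros((n, n), dtype=np.int64)
    for u, v in net.arcs:
        a[net.index(v), net.index(u)] = 1
    return a


def ancestors_within(net: DirectedNetwork, node: str, distance: int) -> set[str]:
    """Nodes with a directed path of length <= ``distance`` to ``node``.

    ``node`` itself is included at distance 0 (a target may serve as its own
    controller). Computed by breadth-first search on reversed arcs.
    """
    if node not in net:
        raise UnknownNodeError(f"unknown node id: {node!r}")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    dist = nx.single_source_shortest_path_length(
        net.graph.reverse(copy=False), node, cutoff=distance
    )
    return set(dist)


def remove_isolated(net: DirectedNetwork) -> DirectedNetwork:
    """Drop nodes with zero in- and out-degree (a self-loop counts as both)."""
    g = net.graph
    keep = [v for v in net.nodes if g.in_degree(v) > 0 or g.out_degree(v) > 0]
    return DirectedNetwork(nodes=keep, arcs=net.arcs)


# -- control problem -------------------------------------------------------


@dataclass(frozen=True)
class ControlProblem:
    """A target controllability instance: network, target list T, preferred set P.

    The targets are an ordered list of distinct network nodes; the preferred
    set (e.g. proteins targetable by approved drugs) may be empty and biases
    the optimizers' choice of input nodes.
    """

    network: DirectedNetwork
    targets: tuple[str, ...]
    preferred: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "preferred", frozenset(self.preferred))
        if not self.targets:
            raise ValueError("T non-empty: at least one target is required")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("target list contains duplicates")
        for t in self.targets:
            if t not in self.network:
                raise UnknownNodeError(f"unknown node id: {t!r} (target)")
        for p in self.preferred:
            if p not in self.network:
                raise UnknownNodeError(f"unknown node id: {p!r} (preferred)")

    @property
    def n_targets(self) -> int:
        return len(self.targets)


# -- text I/O ---------------------------------------------------------------


def read_edge_list(stream: IO[str]) -> DirectedNetwork:
    """Parse a two-column edge list (whitespace-delimited, '#' comments).

    Node order is the order of first appearance; duplicate arcs are collapsed
    (the count is logged).
    """
    arcs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise NetworkFormatError(
                f"line {lineno}: expected 'source target', got {line!r}"
            )
        arcs.append((fields[0], fields[1]))
    if not arcs:
        raise NetworkFormatError("no edges")
    return DirectedNetwork(arcs=arcs)


def write_edge_list(net: DirectedNetwork, stream: IO[str]) -> None:
    """Write one ``source<TAB>target`` line per arc, in arc order."""
    for u, v in net.arcs:
        stream.write(f"{u}\t{v}\n")


def read_node_set(stream: IO[str], net: DirectedNetwork) -> list[str]:
    """Parse a one-id-per-line node set; order preserved, duplicates dropped
    with a warning; ids must belong to ``net``."""
    out: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        node = line.split()[0]
        if node not in net:
            raise UnknownNodeError(f"unknown node id: {node!r} (line {lineno})")
        if node in seen:
            logger.warning("duplicate node id %r at line %d ignored", node, lineno)
            continue
        seen.add(node)
        out.append(node)
    return out
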