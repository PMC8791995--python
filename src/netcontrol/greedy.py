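"""Greedy baseline: iterated maximum matching of control paths.

One control path is grown per target, elongating upstream against arc
direction. Each round matches current path heads to candidate extenders
(predecessors not already used as extenders and not on the path itself) by
maximum bipartite matching, in two phases: preferred extenders first, then
the remaining heads against all extenders (already-matched heads stay
matched). Unmatched heads finalize their path. A finalized head becomes an
input node, unless it is itself another target: then control chains through
that target's own path. Because a node enters ``used_heads`` the first time
it extends a path, chained targets form linear chains under each ultimate
input with strictly increasing control distances, so the resulting input
set passes the Kalman rank condition (which is re-checked after every run).

Run-to-run variability comes solely from seeded tie-breaking among maximum
matchings; the constrained variant additionally finalizes any path reaching
``max_path`` arcs.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .controllability import KalmanValidator, RankTestConfig
from .network import ControlProblem, DirectedNetwork
from .results import InputSetSolution

logger = logging.getLogger(__name__)

__all__ = ["matching_round", "greedy_run", "greedy_iteration"]


def _shuffled(items: Sequence, rng: np.random.Generator) -> list:
    items = list(items)
    if len(items) > 1:
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
    return items


def _augment(
    key,
    adj: Mapping,
    allowed,
    head_match: dict,
    ext_match: dict,
    visited: set,
) -> bool:
    """Kuhn augmenting path from an unmatched head (warm-start friendly)."""
    for u in adj[key]:
        if u in visited or not allowed(u):
            continue
        visited.add(u)
        other = ext_match.get(u)
        if other is None or _augment(other, adj, allowed, head_match, ext_match, visited):
            ext_match[u] = key
            head_match[key] = u
            return True
    return False


def _two_phase_matching(
    adj: Mapping, preferred: frozenset, rng: np.random.Generator
) -> dict:
    """Maximum matching head->extender, preferring preferred extenders.

    Phase 1 computes a maximum matching on the preferred-only subgraph;
    phase 2 augments to an overall maximum matching without unmatching any
    head (augmenting paths only reroute extenders). Ties among maximum
    matchings are broken by seeded shuffling of head and adjacency order.
    """
    keys = _shuffled(list(adj), rng)
    adj = {k: _shuffled(adj[k], rng) for k in keys}
    head_match: dict = {}
    ext_match: dict = {}
    for k in keys:
        if k not in head_match:
            _augment(k, adj, lambda u: u in preferred, head_match, ext_match, set())
    for k in keys:
        if k not in head_match:
            _augment(k, adj, lambda u: True, head_match, ext_match, set())
    return head_match


def matching_round(
    active_heads: Sequence[str],
    net: DirectedNetwork,
    preferred: frozenset[str] | set[str],
    used_heads: set[str],
    rng: np.random.Generator,
    path_nodes: Mapping[str, set[str]] | None = None,
) -> dict[str, str]:
    """One elongation round: match each active head to a distinct extender.

    Candidate extenders of head ``h`` are predecessors of ``h`` not in
    ``used_heads`` and not among ``path_nodes[h]`` (the nodes already on
    h's own path). Returns a partial map head -> extender.
    """
    if not active_heads:
        raise ValueError("active_heads must be non-empty")
    adj = {}
    for h in active_heads:
        own = path_nodes.get(h, {h}) if path_nodes is not None else {h}
        adj[h] = [u for u in net.predecessors(h) if u not in used_heads and u not in own]
    return _two_phase_matching(adj, frozenset(preferred), rng)


def greedy_run(
    problem: ControlProblem,
    max_path: int | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    post_verify: bool = True,
) -> InputSetSolution:
    """One greedy solve. ``max_path=None`` leaves path lengths unconstrained."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    net = problem.network
    targets = problem.targets
    target_set = set(targets)
    # paths keyed by target; head at position 0
    paths: dict[str, list[str]] = {t: [t] for t in targets}
    finalized: dict[str, bool] = {t: False for t in targets}
    used_heads: set[str] = set()

    while not all(finalized.values()):
        active = [t for t in targets if not finalized[t]]
        adj = {}
        for t in active:
            h = paths[t][0]
            own = set(paths[t])
            adj[t] = [u for u in net.predecessors(h) if u not in used_heads and u not in own]
        matching = _two_phase_matching(adj, problem.preferred, rng)
        for t in active:
            u = matching.get(t)
            if u is None:
                finalized[t] = True
            else:
                paths[t].insert(0, u)
                used_heads.add(u)
                if max_path is not None and len(paths[t]) - 1 >= max_path:
                    finalized[t] = True

    heads = {t: paths[t][0] for t in targets}

    # resolve chained heads: a head that is another target is controlled
    # through that target's own path; cycles (mutual chaining) are broken by
    # promoting the lexicographically-by-index smallest head to an input.
    anchor: dict[str, str] = {}

    def ultimate(t: str, trail: tuple[str, ...] = ()) -> str:
        if t in anchor:
            return anchor[t]
        h = heads[t]
        if h in target_set and h != t:
            if h in trail:  # chaining cycle
                members = trail[trail.index(h):] + (h,)
                promoted = min((heads[m] for m in members), key=net.index)
                for m in members:
                    anchor[m] = promoted
                return promoted
            res = ultimate(h, trail + (t,))
        else:
            res = h
        anchor[t] = res
        return res

    assignment = {t: ultimate(t) for t in targets}
    inputs = frozenset(assignment.values())
    lengths = {t: len(paths[t]) - 1 for t in targets}
    tag = "greedy-unconstrained" if max_path is None else "greedy-constrained"
    solution = InputSetSolution(
        inputs=inputs,
        assignment=assignment,
        path_lengths=lengths,
        algorithm=tag,
        seed=seed,
    )
    if post_verify:
        cfg = RankTestConfig(horizon=max(net.n_nodes - 1, 1))
        if not KalmanValidator(net, targets, cfg, seed=0).is_controllable(inputs):
            logger.warning(
                "greedy solution %s failed the Kalman post-check", sorted(inputs)
            )
    return solution


def greedy_iteration(
    problem: ControlProblem,
    max_path: int | None = None,
    runs: int = 80,
    seed: int = 0,
    post_verify: bool = True,
) -> list[InputSetSolution]:
    """A bundle of independently seeded greedy runs.

    The greedy yields a single solution per run; a bundle of 80 runs is the
    unit comparable to one GA run with a population of 80.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    out = []
    for r in range(runs):
        rng = np.random.default_rng([seed, r])
        out.append(
            greedy_run(problem, max_path=max_path, rng=rng, seed=seed, post_verify=post_verify)
        )
    return out
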