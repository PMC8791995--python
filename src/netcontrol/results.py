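"""Shared solution container for the GA and greedy solvers."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class InputSetSolution:
    """One solution to a target controllability instance.

    inputs
        The distinct driver nodes.
    assignment
        target -> the input node ultimately responsible for controlling it.
    path_lengths
        target -> length (arcs) of the recorded control path for that
        target. For the GA this is the BFS distance from the assigned
        controller; for the greedy it is the length of the target's own
        constructed path segment (chained segments are not summed).
    algorithm
        Free-form provenance tag ("ga", "greedy-constrained", ...).
    seed
        Seed of the run that produced the solution.
    """

    inputs: frozenset[str]
    assignment: Mapping[str, str] = field(default_factory=dict)
    path_lengths: Mapping[str, int] = field(default_factory=dict)
    algorithm: str = ""
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "assignment", dict(self.assignment))
        object.__setattr__(self, "path_lengths", dict(self.path_lengths))

    @property
    def size(self) -> int:
        return len(self.inputs)

    def n_preferred(self, preferred) -> int:
        """Number of inputs that are preferred nodes."""
        return len(self.inputs & frozenset(preferred))

    def n_targets_by_preferred(self, preferred) -> int:
        """Number of targets whose assigned controller is preferred."""
        pref = frozenset(preferred)
        return sum(1 for c in self.assignment.values() if c in pref)

    def to_dict(self) -> dict:
        return {
            "inputs": sorted(self.inputs),
            "size": self.size,
            "assignment": dict(self.assignment),
            "path_lengths": dict(self.path_lengths),
            "algorithm": self.algorithm,
            "seed": self.seed,
        }
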