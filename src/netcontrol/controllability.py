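"""Structural target controllability via the Kalman rank condition.

An input set I controls a target set T of a linear network dynamics
x' = A x + B u (B the 0/1 node-selection matrix with one column per input)
iff the target rows of the Kalman matrix [B, AB, A^2 B, ...] have full rank
|T| for a generic choice of nonzero arc weights. The generic (structural)
rank equals the rank attained for almost every random weight assignment; we
evaluate it exactly over a large prime field GF(p), so the test needs no
floating-point tolerance and is bit-reproducible for a fixed seed. By the
Schwartz-Zippel bound the error is one-sided (a structurally controllable
instance can be misjudged "false" with probability at most about
|T| * horizon / p per draw); repeated independent draws make it negligible.

The matrix-power horizon doubles as the bound on the number of interactions
allowed on a control path: a node more than ``horizon`` arcs upstream of
every target contributes nothing to the truncated Kalman matrix.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import ControlProblem, DirectedNetwork

__all__ = [
    "DEFAULT_FIELD_PRIME",
    "RankTestConfig",
    "KalmanValidator",
    "gf_rank",
    "control_matrix",
    "is_target_controllable",
    "minimal_input_oracle",
]

#: Mersenne prime 2^31 - 1; squares still fit in int64 during elimination.
DEFAULT_FIELD_PRIME = 2_147_483_647


@dataclass(frozen=True)
class RankTestConfig:
    """Parameters of the randomized exact rank test.

    horizon
        Maximum matrix power (= arcs allowed on a control path), >= 1.
    field_prime
        Prime modulus of the evaluation field; must exceed 10**6 so the
        one-sided failure probability stays tiny.
    draws
        Number of independent random weight assignments; the verdict is
        "controllable" if any draw reaches full target-row rank.
    """

    horizon: int = 5
    field_prime: int = DEFAULT_FIELD_PRIME
    draws: int = 3

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.field_prime <= 10**6:
            raise ValueError("field_prime must exceed 10**6")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


def gf_rank(mat: np.ndarray, p: int) -> int:
    """Rank of an integer matrix over GF(p) by Gaussian elimination.

    Entries are reduced mod p; products of two reduced entries must fit in
    int64, which holds for p <= 2^31 - 1.
    """
    m = np.array(mat, dtype=np.int64) % p
    rows, cols = m.shape
    r = 0
    for c in range(cols):
        if r == rows:
            break
        pivots = np.nonzero(m[r:, c])[0]
        if pivots.size == 0:
            continue
        i = r + int(pivots[0])
        if i != r:
            m[[r, i]] = m[[i, r]]
        inv = pow(int(m[r, c]), p - 2, p)
        m[r] = (m[r] * inv) % p
        below = m[r + 1 :, c]
        if below.size:
            m[r + 1 :] = (m[r + 1 :] - np.outer(below, m[r])) % p
        r += 1
    return r


def control_matrix(
    A: np.ndarray,
    inputs: Sequence[int],
    targets: Sequence[int],
    horizon: int,
) -> np.ndarray:
    """Target rows of the truncated Kalman matrix [B, AB, ..., A^horizon B].

    ``A`` is a (possibly weighted) adjacency matrix with ``A[v, u]`` the
    weight of arc u -> v; ``B`` has one indicator column per entry of
    ``inputs``. Returns a |targets| x (|inputs| * (horizon + 1)) matrix with
    columns grouped block-wise by power.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A must be square")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    t_idx = list(targets)
    i_idx = list(inputs)
    B = np.zeros((n, len(i_idx)), dtype=A.dtype)
    for col, i in enumerate(i_idx):
        B[i, col] = 1
    blocks = []
    M = B
    for _ in range(horizon + 1):
        blocks.append(M[t_idx, :])
        M = A @ M
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((len(t_idx), 0))


class KalmanValidator:
    """Reusable rank tester for a fixed (network, targets, config, seed).

    Precomputes, per draw, the target rows of A^k for k = 0..horizon under a
    random GF(p) weighting of the arcs (weights keyed by arc index, so the
    verdict is stable across runs and platforms). Checking an input set then
    reduces to slicing input columns and one small exact rank computation.
    Column weights on B are nonzero field elements and cannot change the
    rank, but are applied for fidelity to the randomized model.
    """

    def __init__(
        self,
        net: DirectedNetwork,
        targets: Sequence[str],
        cfg: RankTestConfig = RankTestConfig(),
        seed: int = 0,
    ):
        if not targets:
            raise ValueError("targets must be non-empty")
        self.net = net
        self.cfg = cfg
        self.targets = tuple(targets)
        self._l = len(self.targets)
        p = cfg.field_prime
        n = net.n_nodes
        t_idx = np.array([net.index(t) for t in self.targets])
        src = np.array([net.index(u) for u, _ in net.arcs], dtype=np.intp)
        dst = np.array([net.index(v) for _, v in net.arcs], dtype=np.intp)
        self._draw_data: list[tuple[np.ndarray, np.ndarray]] = []
        for d in range(cfg.draws):
            rng = np.random.default_rng([seed, d])
            A = np.zeros((n, n), dtype=np.int64)
            if len(src):
                A[dst, src] = rng.integers(1, p, size=len(src), dtype=np.int64)
            wb = rng.integers(1, p, size=n, dtype=np.int64)
            S = np.empty((cfg.horizon + 1, self._l, n), dtype=np.int64)
            S[0] = 0
            S[0, np.arange(self._l), t_idx] = 1
            for k in range(1, cfg.horizon + 1):
                S[k] = (S[k - 1] @ A) % p
            self._draw_data.append((S, wb))

    def is_controllable(self, inputs: Sequence[str]) -> bool:
        """True iff the distinct input nodes control every target."""
        idx = sorted({self.net.index(i) for i in inputs})
        if not idx:
            return False
        p = self.cfg.field_prime
        for S, wb in self._draw_data:
            M = S[:, :, idx].transpose(1, 0, 2).reshape(self._l, -1)
            colw = np.tile(wb[idx], self.cfg.horizon + 1)
            M = (M * colw) % p
            if gf_rank(M, p) == self._l:
                return True
        return False


def is_target_controllable(
    net: DirectedNetwork,
    inputs: Sequence[str],
    targets: Sequence[str],
    cfg: RankTestConfig = RankTestConfig(),
    seed: int = 0,
) -> bool:
    """One-shot wrapper around :class:`KalmanValidator`.

    Returns False for an empty input set (when T is non-empty). Error is
    one-sided: a "true" verdict is certain, a "false" verdict is wrong with
    negligible probability.
    """
    return KalmanValidator(net, targets, cfg, seed).is_controllable(inputs)


def minimal_input_oracle(
    problem: ControlProblem,
    horizon: int,
    seed: int = 0,
    draws: int = 3,
    max_nodes: int = 15,
) -> int:
    """Exact minimum input-set size by exhaustive subset enumeration.

    Brute-force reference for small instances only (the problem is NP-hard);
    refuses networks larger than ``max_nodes``. Enumerates subsets in order
    of increasing size, so the first controllable subset is minimal. Since
    I = T is always controllable the answer is at most |T|.
    """
    net = problem.network
    if net.n_nodes > max_nodes:
        raise ValueError(
            f"network has {net.n_nodes} nodes; oracle is limited to {max_nodes}"
        )
    cfg = RankTestConfig(horizon=horizon, draws=max(draws, 3))
    validator = KalmanValidator(net, problem.targets, cfg, seed)
    for size in range(1, net.n_nodes + 1):
        for subset in itertools.combinations(net.nodes, size):
            if validator.is_controllable(subset):
                return size
    raise AssertionError("unreachable: I = T always controls T")
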