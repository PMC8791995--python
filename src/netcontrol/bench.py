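"""Benchmark harness: summary metrics and cross-algorithm comparison.

Reproduces the comparison axes used for benchmarking the solvers: number of
distinct solutions per run, solution sizes, control-path lengths, preferred
input statistics, and the frequency with which individual input nodes recur
across repeated runs.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd

from .controllability import KalmanValidator, RankTestConfig
from .ga import GAParams, evolve
from .greedy import greedy_iteration
from .network import ControlProblem
from .results import InputSetSolution

__all__ = [
    "BenchmarkRecord",
    "summarize",
    "frequency_buckets",
    "compare_experiment",
    "FREQUENCY_BUCKETS",
]

#: Bucket labels for input-recurrence counts over 10 runs.
FREQUENCY_BUCKETS = ("9-10", "7-8", "5-6", "3-4", "1-2")


@dataclass(frozen=True)
class BenchmarkRecord:
    """Aggregated metrics for one pool of solutions (one run/iteration)."""

    network: str = ""
    model: str = ""
    n_nominal: int = 0
    algorithm: str = ""
    variant: str = ""
    max_path: int | None = None
    iteration: int = 0
    n_solutions: int = 0
    min_size: int = 0
    mean_size: float = 0.0
    mean_path_len: float = 0.0
    max_path_len: int = 0
    n_preferred_inputs: float = 0.0
    n_targets_by_preferred: float = 0.0
    generations: int | None = None
    seed: int | None = None


def summarize(
    solutions: Sequence[InputSetSolution],
    preferred,
    **meta,
) -> BenchmarkRecord:
    """Collapse a pool of solutions into one record.

    Counts distinct input sets (set-of-sets semantics), size statistics, the
    pooled path-length distribution, and the preferred-input statistics
    (averaged over the distinct solutions). Extra keyword arguments fill the
    record's descriptive fields.
    """
    if not solutions:
        raise ValueError("solutions must be non-empty")
    preferred = frozenset(preferred)
    distinct: dict[frozenset, InputSetSolution] = {}
    for s in solutions:
        distinct.setdefault(s.inputs, s)
    pool = list(distinct.values())
    sizes = [s.size for s in pool]
    lengths = [d for s in pool for d in s.path_lengths.values()]
    n_pref = [s.n_preferred(preferred) for s in pool]
    n_tbp = [s.n_targets_by_preferred(preferred) for s in pool]
    return BenchmarkRecord(
        n_solutions=len(pool),
        min_size=min(sizes),
        mean_size=sum(sizes) / len(sizes),
        mean_path_len=(sum(lengths) / len(lengths)) if lengths else 0.0,
        max_path_len=max(lengths) if lengths else 0,
        n_preferred_inputs=sum(n_pref) / len(n_pref),
        n_targets_by_preferred=sum(n_tbp) / len(n_tbp),
        algorithm=pool[0].algorithm,
        **meta,
    )


def frequency_buckets(
    run_solutions: Sequence[Sequence[InputSetSolution]],
) -> dict[str, int]:
    """Bucket input nodes by how many of 10 runs identified them.

    ``run_solutions`` holds the solution pool of each of exactly 10 runs; a
    node counts as identified in a run if it appears in any of that run's
    input sets. Buckets partition the observed nodes.
    """
    if len(run_solutions) != 10:
        raise ValueError("frequency_buckets requires exactly 10 runs")
    counts: dict[str, int] = {}
    for run in run_solutions:
        seen = set()
        for s in run:
            seen |= s.inputs
        for v in seen:
            counts[v] = counts.get(v, 0) + 1
    hist = {b: 0 for b in FREQUENCY_BUCKETS}
    for c in counts.values():
        if c >= 9:
            hist["9-10"] += 1
        elif c >= 7:
            hist["7-8"] += 1
        elif c >= 5:
            hist["5-6"] += 1
        elif c >= 3:
            hist["3-4"] += 1
        else:
            hist["1-2"] += 1
    return hist


def _verify_all(problem: ControlProblem, solutions: Sequence[InputSetSolution]) -> None:
    cfg = RankTestConfig(horizon=max(problem.network.n_nodes - 1, 1))
    validator = KalmanValidator(problem.network, problem.targets, cfg, seed=0)
    for s in solutions:
        if not validator.is_controllable(s.inputs):
            raise AssertionError(f"solution {sorted(s.inputs)} fails the rank test")


def compare_experiment(
    problem: ControlProblem,
    ga_params: GAParams = GAParams(),
    greedy_runs: int = 80,
    iterations: int = 10,
    seed: int = 0,
    network_name: str = "",
    model: str = "",
    n_nominal: int = 0,
    post_verify: bool = False,
) -> pd.DataFrame:
    """Run GA vs constrained greedy vs unconstrained greedy, repeatedly.

    Per iteration: one GA run (its final minimal solutions), one bundle of
    ``greedy_runs`` constrained greedy runs (same max_path as the GA), and
    one bundle of unconstrained runs. Returns one row per (iteration,
    algorithm) with the columns of :class:`BenchmarkRecord`.
    """
    records = []
    meta = dict(network=network_name, model=model, n_nominal=n_nominal)
    for it in range(1, iterations + 1):
        it_seed = seed * 1_000 + it
        ga_res = evolve(problem, GAParams(**{**_params_dict(ga_params), "seed": it_seed}))
        pools = [
            (list(ga_res.solutions), "ga", "constrained", ga_params.max_path,
             ga_res.generations_run),
            (greedy_iteration(problem, max_path=ga_params.max_path, runs=greedy_runs,
                              seed=it_seed, post_verify=False),
             "greedy", "constrained", ga_params.max_path, None),
            (greedy_iteration(problem, max_path=None, runs=greedy_runs,
                              seed=it_seed, post_verify=False),
             "greedy", "unconstrained", None, None),
        ]
        for sols, algo, variant, mp, gens in pools:
            if post_verify:
                _verify_all(problem, sols)
            rec = summarize(
                sols, problem.preferred, iteration=it, variant=variant,
                max_path=mp, generations=gens, seed=it_seed, **meta,
            )
            records.append({**asdict(rec), "algorithm": algo})
    return pd.DataFrame.from_records(records)


def _params_dict(p: GAParams) -> dict:
    return {f: getattr(p, f) for f in p.__dataclass_fields__}
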