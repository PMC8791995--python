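"""Genetic algorithm for structural target controllability.

A chromosome assigns one controller ("gene") to each target; the gene for
target t_i is drawn from the ancestors of t_i at most ``max_path`` arcs
upstream, with preferred (e.g. drug-targetable) nodes favored with
probability ``preferred_prob``. Every chromosome kept in a population is a
valid solution: its distinct genes pass the Kalman rank test. Evolution
combines elitism, fresh random chromosomes (to escape local optima), and
mutated offspring of roulette-selected parents; fitness rewards few distinct
inputs first and preferred inputs second. The run stops after ``N_prime``
generations without improvement, or at generation ``N``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .controllability import DEFAULT_FIELD_PRIME, KalmanValidator, RankTestConfig
from .network import ControlProblem, ancestors_within
from .results import InputSetSolution

logger = logging.getLogger(__name__)

__all__ = [
    "GAParams",
    "Chromosome",
    "GAResult",
    "candidate_pool",
    "random_gene",
    "random_chromosome",
    "fitness",
    "select",
    "crossover",
    "mutate",
    "evolve",
    "extract_solutions",
]


@dataclass(frozen=True)
class GAParams:
    """GA parameters; defaults are the benchmark configuration.

    N: max generations. N_prime: patience (generations without improvement).
    n: population size. p_m: per-chromosome mutation probability. p_e: elite
    fraction (upper bound). p_r: random-injection fraction. max_path: bound
    on control-path length in arcs (also the Kalman horizon). max_rand: cap
    on distinct freshly drawn genes per chromosome construction (beyond it,
    gene reuse is forced whenever compatible). preferred_prob: probability
    of drawing a preferred candidate. improvement: whether the patience
    counter tracks best "fitness" or best solution "size".
    """

    N: int = 10_000
    N_prime: int = 100
    n: int = 80
    p_m: float = 0.01
    p_e: float = 0.25
    p_r: float = 0.25
    max_path: int = 5
    max_rand: int = 15
    preferred_prob: float = 2 / 3
    seed: int = 0
    rank_draws: int = 3
    field_prime: int = DEFAULT_FIELD_PRIME
    improvement: str = "fitness"

    def __post_init__(self):
        if self.N < 1 or self.N_prime < 1:
            raise ValueError("N and N_prime must be >= 1")
        if self.n < 2:
            raise ValueError("population size n must be >= 2")
        for name in ("p_m", "p_e", "p_r", "preferred_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_e + self.p_r >= 1.0:
            raise ValueError("p_e + p_r must be < 1")
        if self.max_path < 1 or self.max_rand < 1:
            raise ValueError("max_path and max_rand must be >= 1")
        if self.improvement not in ("fitness", "size"):
            raise ValueError("improvement must be 'fitness' or 'size'")

    def rank_config(self) -> RankTestConfig:
        return RankTestConfig(
            horizon=self.max_path, field_prime=self.field_prime, draws=self.rank_draws
        )


@dataclass(frozen=True)
class Chromosome:
    """A per-target controller assignment; always a valid solution."""

    genes: tuple[str, ...]
    inputs: frozenset[str]
    fitness: float

    @property
    def size(self) -> int:
        return len(self.inputs)


@dataclass(frozen=True)
class GAResult:
    """Outcome of one GA run: all minimal distinct input sets of the final
    population, with run diagnostics."""

    solutions: tuple[InputSetSolution, ...]
    generations_run: int
    best_fitness_history: tuple[float, ...]
    best_size_history: tuple[int, ...]

    @property
    def min_size(self) -> int:
        return min(s.size for s in self.solutions)

    def to_dict(self) -> dict:
        return {
            "solutions": [s.to_dict() for s in self.solutions],
            "generations_run": self.generations_run,
            "best_fitness_history": list(self.best_fitness_history),
            "best_size_history": list(self.best_size_history),
        }


def fitness(genes: Sequence[str], problem: ControlProblem) -> float:
    """(l + 1 - d) + 0.5 * p_d / max(d, 1), with d the number of distinct
    genes and p_d the preferred ones among them.

    Strictly decreasing in d; for equal d strictly increasing in p_d; always
    >= 1, so roulette selection is well defined.
    """
    distinct = set(genes)
    d = len(distinct)
    p_d = len(distinct & problem.preferred)
    return (len(problem.targets) + 1 - d) + 0.5 * (p_d / max(d, 1))


class _Engine:
    """Internal GA machinery bound to one (problem, params) pair."""

    def __init__(self, problem: ControlProblem, params: GAParams):
        self.problem = problem
        self.params = params
        net = problem.network
        self.validator = KalmanValidator(
            net, problem.targets, params.rank_config(), seed=params.seed
        )
        # candidate pools per target, in stable node order
        self.pools: dict[str, tuple[list[str], list[str]]] = {}
        self.pool_sets: dict[str, frozenset[str]] = {}
        for t in problem.targets:
            anc = ancestors_within(net, t, params.max_path)
            ordered = sorted(anc, key=net.index)
            pref = [v for v in ordered if v in problem.preferred]
            other = [v for v in ordered if v not in problem.preferred]
            self.pools[t] = (pref, other)
            self.pool_sets[t] = frozenset(anc)
        self._valid_cache: dict[frozenset[str], bool] = {}

    # -- validity ----------------------------------------------------------

    def is_valid(self, genes: Sequence[str]) -> bool:
        key = frozenset(genes)
        hit = self._valid_cache.get(key)
        if hit is None:
            hit = self.validator.is_controllable(key)
            self._valid_cache[key] = hit
        return hit

    def make(self, genes: Sequence[str]) -> Chromosome:
        genes = tuple(genes)
        return Chromosome(genes, frozenset(genes), fitness(genes, self.problem))

    # -- gene / chromosome construction -------------------------------------

    def random_gene(self, target: str, rng: np.random.Generator) -> str:
        pref, other = self.pools[target]
        use_pref = rng.random() < self.params.preferred_prob
        pool = pref if use_pref else other
        if not pool:  # fall back to the other sub-pool (never both empty)
            pool = other if use_pref else pref
        return pool[int(rng.integers(len(pool)))]

    def random_chromosome(self, rng: np.random.Generator, retries: int = 50) -> Chromosome:
        targets = self.problem.targets
        for _ in range(retries):
            genes: list[str] = []
            chosen: set[str] = set()
            fresh: set[str] = set()
            for t in targets:
                pool = self.pool_sets[t]
                compatible = sorted(chosen & pool, key=self.problem.network.index)
                force_reuse = len(fresh) >= self.params.max_rand
                if compatible and (force_reuse or rng.random() < 0.5):
                    g = compatible[int(rng.integers(len(compatible)))]
                else:
                    g = self.random_gene(t, rng)
                    if g not in chosen:
                        fresh.add(g)
                genes.append(g)
                chosen.add(g)
            if self.is_valid(genes):
                return self.make(genes)
        # fallback: each target drives itself (always valid)
        return self.make(targets)

    # -- variation operators -------------------------------------------------

    def crossover(
        self, a: Chromosome, b: Chromosome, rng: np.random.Generator, attempts: int = 10
    ) -> Chromosome:
        l = len(a.genes)
        for _ in range(attempts):
            mask = rng.integers(0, 2, size=l)
            genes = tuple(a.genes[i] if mask[i] else b.genes[i] for i in range(l))
            if self.is_valid(genes):
                return self.make(genes)
        return a if a.fitness >= b.fitness else b

    def mutate(
        self, c: Chromosome, rng: np.random.Generator, attempts: int = 10
    ) -> Chromosome:
        if rng.random() >= self.params.p_m:
            return c
        l = len(c.genes)
        for _ in range(attempts):
            i = int(rng.integers(l))
            g = self.random_gene(self.problem.targets[i], rng)
            genes = c.genes[:i] + (g,) + c.genes[i + 1 :]
            if self.is_valid(genes):
                return self.make(genes)
        return c

    # -- solution decoding ----------------------------------------------------

    def decode(self, population: Sequence[Chromosome], seed: int | None) -> tuple[InputSetSolution, ...]:
        best_size = min(c.size for c in population)
        reps: dict[frozenset[str], Chromosome] = {}
        for c in population:
            if c.size == best_size and c.inputs not in reps:
                reps[c.inputs] = c
        g = self.problem.network.graph
        out = []
        for inputs, c in reps.items():
            assignment = dict(zip(self.problem.targets, c.genes))
            lengths = {
                t: nx.shortest_path_length(g, source=ctrl, target=t)
                for t, ctrl in assignment.items()
            }
            out.append(
                InputSetSolution(
                    inputs=inputs,
                    assignment=assignment,
                    path_lengths=lengths,
                    algorithm="ga",
                    seed=seed,
                )
            )
        return tuple(out)


# -- public per-operation wrappers (thin, for testing and reuse) -------------


def candidate_pool(
    problem: ControlProblem, target: str, max_path: int
) -> tuple[list[str], list[str]]:
    """Partition the ancestors of ``target`` within ``max_path`` arcs into
    (preferred, other) lists in stable node order."""
    net = problem.network
    ordered = sorted(ancestors_within(net, target, max_path), key=net.index)
    pref = [v for v in ordered if v in problem.preferred]
    other = [v for v in ordered if v not in problem.preferred]
    return pref, other


def random_gene(
    problem: ControlProblem, target: str, params: GAParams, rng: np.random.Generator
) -> str:
    return _Engine(problem, params).random_gene(target, rng)


def random_chromosome(
    problem: ControlProblem, params: GAParams, rng: np.random.Generator
) -> Chromosome:
    return _Engine(problem, params).random_chromosome(rng)


def select(population: Sequence[Chromosome], rng: np.random.Generator) -> Chromosome:
    """Roulette-wheel selection: probability proportional to fitness."""
    if not population:
        raise ValueError("population must be non-empty")
    weights = np.array([c.fitness for c in population], dtype=float)
    cum = np.cumsum(weights)
    u = rng.random() * cum[-1]
    return population[int(np.searchsorted(cum, u, side="right"))]


def crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    problem: ControlProblem,
    params: GAParams,
    rng: np.random.Generator,
) -> Chromosome:
    return _Engine(problem, params).crossover(parent_a, parent_b, rng)


def mutate(
    chromosome: Chromosome,
    problem: ControlProblem,
    params: GAParams,
    rng: np.random.Generator,
) -> Chromosome:
    return _Engine(problem, params).mutate(chromosome, rng)


def extract_solutions(population: Sequence[Chromosome]) -> set[frozenset[str]]:
    """Distinct input sets of minimal size within a population."""
    if not population:
        raise ValueError("population must be non-empty")
    best = min(c.size for c in population)
    return {c.inputs for c in population if c.size == best}


# -- the generation loop -----------------------------------------------------


def evolve(
    problem: ControlProblem,
    params: GAParams = GAParams(),
    on_generation: Callable[[int, list[Chromosome]], None] | None = None,
) -> GAResult:
    """Run the GA and return the minimal input sets of the final population.

    ``on_generation(t, population)`` is invoked after every generation
    (including the initial one) and is intended for logging and invariant
    checking.
    """
    engine = _Engine(problem, params)
    rng = np.random.default_rng([params.seed, 987_654_321])
    n = params.n

    population = [engine.random_chromosome(rng) for _ in range(n)]
    best_fit = max(c.fitness for c in population)
    best_size = min(c.size for c in population)
    fit_history = [best_fit]
    size_history = [best_size]
    if on_generation is not None:
        on_generation(0, population)

    n_elite = math.floor(params.p_e * n)
    n_random = math.floor(params.p_r * n)
    gen = 0
    stagnant = 0
    while gen < params.N and stagnant < params.N_prime:
        gen += 1
        # elites: distinct chromosomes, fitness ties broken uniformly at random
        distinct = {c.genes: c for c in population}
        ranked = sorted(
            distinct.values(), key=lambda c: (-c.fitness, rng.random())
        )
        nxt: list[Chromosome] = ranked[:n_elite]
        nxt.extend(engine.random_chromosome(rng) for _ in range(min(n_random, n - len(nxt))))
        while len(nxt) < n:
            a = select(population, rng)
            b = select(population, rng)
            nxt.append(engine.mutate(engine.crossover(a, b, rng), rng))
        population = nxt

        gen_fit = max(c.fitness for c in population)
        gen_size = min(c.size for c in population)
        if params.improvement == "fitness":
            improved = gen_fit > best_fit
        else:
            improved = gen_size < best_size
        stagnant = 0 if improved else stagnant + 1
        best_fit = max(best_fit, gen_fit)
        best_size = min(best_size, gen_size)
        fit_history.append(gen_fit)
        size_history.append(gen_size)
        if on_generation is not None:
            on_generation(gen, population)
        logger.debug(
            "generation %d: best fitness %.3f, best size %d (stagnant %d)",
            gen, gen_fit, gen_size, stagnant,
        )

    return GAResult(
        solutions=engine.decode(population, params.seed),
        generations_run=gen,
        best_fitness_history=tuple(fit_history),
        best_size_history=tuple(size_history),
    )
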