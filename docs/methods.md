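# Methods

## Model and assumptions

The package treats a directed network `G = (V, E)` as the structure of a
linear time-invariant system `x' = A x + B u`: `A[v, u]` is nonzero iff the
arc `(u, v)` exists, and `B` has one 0/1 indicator column per input node.
Interactions are unlabelled — no signs, weights or nonlinearities — which is
the standard setting for structural controllability. An input set `I`
*controls* the target list `T` when the `|T|` target rows of the Kalman
matrix `[B, AB, …, A^h B]` have full rank for a generic assignment of
nonzero weights to the arcs. Under this structural semantics the verdict
depends only on topology, not on kinetic parameters; the price is possible
false positives in a biological reading (a control path may be functionally
weak because of conflicting interaction signs).

Two consequences of the rank condition shape everything downstream:

- a single input can control several targets only if their distances from it
  along the control paths are pairwise distinct (a hub feeding two targets
  at equal distance always fails);
- a node more than `h` arcs upstream of every target contributes nothing to
  the truncated Kalman matrix, so the power horizon `h` and the maximum
  control-path length are one and the same knob.

## Exact generic-rank evaluation

Generic rank equals the rank attained for almost every numeric realization,
so we draw arc weights uniformly from the nonzero elements of GF(p) with
p = 2³¹ − 1 and compute the rank by exact Gaussian elimination mod p
(int64 arithmetic; products of two reduced entries stay below 2⁶³). The
error is one-sided: a controllable instance can be misjudged uncontrollable
with probability at most about `|T|·h / p` per draw (Schwartz–Zippel); with
the default 3 independent draws this is ~10⁻⁸ even on the largest benchmark
instances. There is no floating-point tolerance to tune, and weights are
keyed by (seed, draw, arc index), so verdicts are bit-stable across runs
and platforms. The validator precomputes the target rows of `A^k` once per
(network, targets, seed), reducing each input-set check to a column slice
and one small elimination — the operation the GA performs thousands of
times. Column scalings of `B` cannot change the rank but are applied for
fidelity to the randomized model. Sympy's `DomainMatrix` over GF(p) serves
as an independent oracle for the elimination routine in the test suite.

## Genetic algorithm

Chromosome: a vector `[g_1, …, g_l]` with `g_i` an ancestor of `t_i` within
`max_path` arcs; its distinct genes are the candidate input set, and only
rank-valid chromosomes are ever admitted to a population. Construction
draws genes target by target, reusing an already-chosen compatible gene
with probability 1/2 (forced once `max_rand` distinct fresh genes have been
drawn — reuse pressure is what biases chromosomes toward small input sets),
validates, and retries up to 50 times before falling back to the always
valid self-control assignment `g_i = t_i`.

Fitness is `(l + 1 − d) + ½ · p_d / max(d, 1)` where `d` is the number of
distinct genes and `p_d` the preferred ones among them. The two terms
implement a lexicographic double objective: any reduction in `d` dominates
any preferred-count change (the bonus is at most ½ while a size step is
worth 1), and for equal `d` the fitness is strictly increasing in `p_d`.
The value is always ≥ 1, keeping roulette selection well defined.

Each generation: carry over up to `⌊p_e·n⌋` distinct elites (fitness ties
broken uniformly at random from the seeded stream), inject `⌊p_r·n⌋` fresh
random chromosomes, and fill to exactly `n` with offspring — two roulette
picks, uniform per-position crossover (10 validity retries, then a copy of
the fitter parent), then with probability `p_m` a single-position mutation
(10 retries, else unmutated). The loop stops at generation `N` or after
`N_prime` consecutive generations without improvement; "improvement" is a
strict best-fitness increase by default, with a size-only mode behind
`GAParams.improvement = "size"`. The output is every distinct input set of
minimal size in the final population, with per-target assignments and BFS
path lengths.

Parameter defaults (`GAParams`): `N = 10000` generations (a hard cap that
patience normally preempts), `N_prime = 100`, population `n = 80`,
`p_m = 0.01`, `p_e = 0.25`, `p_r = 0.25`, `max_path = 5` arcs,
`max_rand = 15`, `preferred_prob = 2/3`. The preference probability trades
search efficiency against preferred-input yield: too high and valid
full-rank combinations become hard to find, too low and preferred nodes are
underused. All randomness flows from `GAParams.seed`; runs are
bit-reproducible.

## Greedy baseline

One control path per target is elongated upstream. Each round forms the
bipartite graph of candidate extenders (predecessors of current heads, not
already used as extenders, not on the head's own path) versus active heads
and computes a maximum matching in two phases: maximum matching on
preferred extenders only, then augmentation to overall maximum without
unmatching any head (Kuhn's augmenting paths, which warm-start naturally;
this is why the matching is hand-rolled rather than delegated to a library
routine, whose size is nevertheless used as an oracle in the tests).
Unmatched heads finalize; the constrained variant also finalizes any path
reaching `max_path` arcs. A finalized head becomes an input unless it is
itself another target, in which case control chains through that target's
path. Since a node enters the used-extender set on first use, chained
targets form linear chains with strictly increasing distances from their
ultimate input, so the construction cannot collide two targets at equal
distance; the rare mutual-chaining cycle (targets heading each other's
paths) is broken by promoting one head, chosen by smallest node index, to
an input. Every run is post-verified with the full-horizon rank test and a
warning is logged on failure (none has been observed in the suite's random
instances). Run-to-run variability comes only from seeded shuffling among
tied maximum matchings; a bundle of 80 independently seeded runs is the
unit comparable to one GA run with population 80.

The per-target `path_lengths` of a greedy solution record the target's own
constructed segment; for a chained target the distance from the ultimate
input is the sum along the chain and can exceed `max_path` even in the
constrained variant, which is why the post-check uses the unconstrained
horizon `n − 1`.

## Synthetic benchmark data

Generators mirror the standard benchmark families: directed G(n, p) with
p = 0.005, directed preferential attachment (mixture α = 0.41, β = 0.54,
γ = 0.05, δ_in = 0.2, δ_out = 0), and a Watts–Strogatz ring (k = 4, rewire
0.2) converted to a digraph by doubling each edge — hence exactly `n·k`
arcs for every seed. Isolated nodes are removed after generation; target
counts are 5% of the *nominal* pre-removal node count, drawn among nodes
with positive in-degree. Random networks have no intrinsic preferred set;
`mark_preferred` labels a random fraction for exercising the preference
machinery and is explicitly synthetic. These graphs emulate the degree
structure of the benchmark families but none of the features of curated
interaction data — no hub-pathway correlation, no preferred nodes
clustered near disease genes, no edge signs — so green tests demonstrate
algorithmic correctness and the direction of effects, not effect sizes on
real disease networks.

## Problem sizes in the test and acceptance runs

Exhaustive-oracle comparisons use networks of 8–12 nodes with 2–4 targets
(subset enumeration is exponential); GA loop invariants and benchmark
comparisons run on small-world networks of 100 nominal nodes with 5
targets; monotonicity properties sample 100 random instances of ≤ 10
nodes; the preference effect uses parallel 3-arc chains with one preferred
and one unpreferred optimum per target, 20 paired seeds, and a one-sided
sign test. The acceptance script repeats these at slightly reduced counts
(15 oracle instances, 10 preference pairs) and one small-world benchmark
iteration.

## Known limitations

- The greedy reconstruction implements the documented behavior (upstream
  elongation, iterated two-phase maximum matching, unmatched heads become
  inputs, optional length bound) but published variants differ in corner
  rules, e.g. whether a node may head paths in different distance classes;
  the stricter single-head rule used here is conservative.
- The GA folds the double objective into one scalar fitness; there is no
  Pareto front, and no adaptive parameter schedules or island populations.
- Percentage-level performance gaps between the algorithms on large or
  biological networks depend on the network corpus and seeds and are out of
  scope here; the suite asserts directions of effects on synthetic
  instances only.
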