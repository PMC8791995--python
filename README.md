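# netcontrol

Minimal input-node selection for **structural target controllability** of
directed networks, with a genetic algorithm that favors *preferred*
(e.g. drug-targetable) nodes.

## The problem

Given a directed network `G = (V, E)` — typically a disease-specific directed
protein–protein interaction network — a list of target nodes
`T = {t_1, …, t_l} ⊆ V` (e.g. survivability-essential genes) and an optional
set `P ⊆ V` of preferred nodes (e.g. targets of approved drugs), find a small
input set `I ⊆ V` such that the linear dynamics

```
x'(t) = A x(t) + B u(t)
```

is controllable on the targets, where `A` is the (weighted) adjacency matrix
and `B` selects the input nodes. Structurally, `I` controls `T` iff the
target rows of the Kalman matrix

```
K = [B, AB, A²B, …, A^h B]
```

have full rank `|T|` for a generic choice of nonzero arc weights. The power
bound `h` doubles as a cap on the number of interactions along a control
path — a biologically meaningful constraint, since drug effects dissipate
over long signaling cascades. Minimizing `|I|` is NP-hard; maximizing
`|I ∩ P|` is a secondary objective that makes solutions actionable for drug
repurposing.

## What the package provides

- **`netcontrol.controllability`** — an exact randomized Kalman rank test:
  arc weights are drawn from the prime field GF(2³¹−1) and the rank is
  computed by exact modular elimination, so there is no floating-point
  tolerance and the verdict is reproducible per seed (error is one-sided and
  negligible, by Schwartz–Zippel). Plus a brute-force minimal-input oracle
  for small instances.
- **`netcontrol.ga`** — the genetic algorithm. A chromosome assigns one
  controller gene `g_i` (an ancestor within `max_path` arcs) to each target
  `t_i`; every chromosome in every population is a *valid* solution (checked
  by the rank test). Fitness `(l + 1 − d) + ½·p_d/d` rewards few distinct
  genes `d` first and preferred genes `p_d` second. Evolution uses elitism,
  fresh random chromosomes, roulette selection, uniform crossover and
  per-chromosome mutation; it stops after `N' = 100` generations without
  improvement.
- **`netcontrol.greedy`** — the baseline: control paths grown upstream from
  the targets by iterated maximum bipartite matching (preferred extenders
  matched first), in path-length-constrained and unconstrained variants.
- **`netcontrol.generators`** — seeded Erdős–Rényi, directed scale-free and
  small-world benchmark generators, 5% target selection among nodes with
  positive in-degree, and random edge-removal perturbation.
- **`netcontrol.bench`** — the GA-vs-greedy comparison harness and
  input-recurrence frequency buckets.

## Worked example

```
$ netcontrol generate --model sw --nodes 100 --seed 1 --out sw100.tsv --targets-out targets.txt
model=sw nominal_n=100 n_nodes=100 n_arcs=400 n_targets=5

$ netcontrol ga --network sw100.tsv --targets targets.txt --seed 1 --out ga.json
$ netcontrol greedy --network sw100.tsv --targets targets.txt --max-path 5 --runs 80 --seed 1 --out greedy.json
```

The small-world generator keeps exactly `nominal_n · k = 400` arcs (each
undirected lattice edge becomes two opposite arcs; rewiring preserves the
count), and 5% of the 100 nominal nodes become targets. On this instance the
GA run (population 80, defaults) reports

```
generations_run: 100
n_solutions: 24
best: 2 ['n36', 'n78']  {'n3': 'n36', 'n45': 'n36', 'n49': 'n36', 'n74': 'n78', 'n94': 'n36'}
```

i.e. 24 distinct minimal input sets of size 2 — node `n36` controls four of
the five targets through distinct-length control paths and `n78` the fifth —
while the bundle of 80 constrained greedy runs returns solutions of sizes
4–5. The result JSON records, per solution, the input set, the per-target
controller assignment and the control-path lengths, plus the full config and
seed needed to reproduce the run bit-for-bit.

CLI exit codes follow click's convention: 0 on success, 2 for usage errors,
1 for runtime/data errors.

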