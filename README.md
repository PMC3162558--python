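# pathevo

Natural selection without template replication: evolution of *paths* through
layered stochastic networks, for researchers in evolutionary computation and
computational neuroscience who want a tested reference implementation of
path-based selection — the path evolution algorithm (PEA) — together with
its microbial-GA baseline, benchmark problems, exact expected-dynamics
models, and a spiking-neuron realization.

## The idea

A layered feed-forward network with one start node carries a population of
paths. Edge weights are transition probabilities (each node's outflow sums
to 1), so stimulating the start node samples one path; the product of
weights along a path is its frequency, and the ordered node labels along it
are its phenotype. Each generation two paths are sampled and their rewards
compared; the winner's private edges are multiplied by `(1 + λ)` and the
loser's by `(1 − λ)` before renormalization — multiplicative growth in
place of replication. Structural plasticity supplies heredity with
variation: a mutated node gains a weakly weighted bypass (a new node, or a
graft onto existing material in its layer), producing new path phenotypes
that remain correlated with their parents'; unused nodes and vanishing
edges are pruned. Because paths overlap, one mutation changes many
phenotypes at once, and the network can hold non-overlapping alternative
routes — linkage disequilibrium — which gives the algorithm memory for past
environments and building-block structure that a population of independent
genotypes lacks.

The package provides:

* `pathevo.network` — the layered substrate: construction, traversal, exact
  path enumeration, phenotype frequencies, plain-text serialization;
* `pathevo.engine` — the tournament loop (`PEAConfig`, `run_pea`) and its
  operators (update, bypass/attachment mutation, two-point crossover,
  pruning);
* `pathevo.ga` — the microbial GA over ordinary genotypes, trace-aligned by
  evaluation count;
* `pathevo.benchmarks` — counting ones, multiple knapsack (+ instance I/O,
  synthetic generator, brute-force oracle), sphere / Rosenbrock / quartic /
  Rastrigin, HIFF, royal road, alternating environments;
* `pathevo.dynamics` — exact expected dynamics on small fixed networks:
  one-locus fixation, two-locus selection, the fully connected two-locus
  network where weight change alone maintains linkage disequilibrium;
* `pathevo.spiking` — Izhikevich regular-spiking grid with winner-take-all
  outputs, dopamine-modulated STDP eligibility traces, activity-dependent
  decay and structural plasticity, solving the 10-bit all-ones task;
* `pathevo.experiments` — figure-caption parameter sets as named recipes,
  seeded batteries, summaries and the environment-memory metric;
* a `pea` command-line interface over all of the above.

## Worked example

```python
from pathevo.network import LayeredPathNetwork
from pathevo.engine import PEAConfig, run_pea, tournament_update
from pathevo.benchmarks import hiff_fitness
from pathevo import dynamics as dyn

# one tournament on a single branch: loser 0.75, winner 0.25, lambda = 0.1
net = LayeredPathNetwork(1)
fav, dis = net.add_node(1, 1), net.add_node(1, 0)
net.add_edge(net.start, fav, 0.25)
net.add_edge(net.start, dis, 0.75)
tournament_update(net, (net.start, fav), (net.start, dis), lam=0.1)
print({"winner": round(net.edge_weight(net.start, fav), 2),
       "loser": round(net.edge_weight(net.start, dis), 2)})

# deterministic one-locus expected dynamics: fitter allele fixates
steps, w = dyn.one_locus_fixation_time(0.1, 0.1, tol=1e-6)
print(f"one-locus fixation: {steps} generations to |w-1| < 1e-6")

# a full optimization run: 16-bit hierarchical if-and-only-if
cfg = PEAConfig(N=10, L=16, lam=0.1, mu=0.01, tau=10000, omega=0.01,
                max_nodes_per_layer=20, generations=50_000, seed=1,
                log_every=500, stop_at_target=True)
trace = run_pea(cfg, hiff_fitness(16))
print(f"16-bit HIFF: optimum 32 first reached at generation "
      f"{trace.first_hit_generation}")
```

prints

```
{'winner': 0.29, 'loser': 0.71}
one-locus fixation: 2750086 generations to |w-1| < 1e-6
16-bit HIFF: optimum 32 first reached at generation 8893
```

The first line is the renormalized multiplicative update (0.25·1.1 and
0.75·0.9, renormalized, to two decimals); the second iterates the exact
one-generation expectation of that update until the favored allele's weight
is within 1e−6 of fixation (fixation is algebraically slow because the
probability of drawing a mixed pair vanishes with the minority weight); the
third shows the full engine assembling a hierarchical building-block
problem from ten random chains.

From the shell, the same machinery is available as:

```
pea run --problem hiff:64 --seed 1 --generations 200000 --out trace.csv
pea run-recipe fig14_hiff --replicates 5 --outdir out/
pea spiking --trials 5000 --seed 0 --out spikes.csv
pea dynamics --model xor --ordering selective --out-prefix xor
```

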