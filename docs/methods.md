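# Methods

## The model

`pathevo` implements natural selection acting on *paths* through a layered,
weighted, feed-forward network — a unit of evolution that grows
multiplicatively instead of replicating. A single start node (layer 0) feeds
`L` phenotype layers; each node carries a label (a binary symbol, or a real
value in [−1, 1]); every node's outgoing weights are kept normalized, so a
stochastic traversal from the start node — choosing one downstream node per
step by roulette-wheel selection over the outflow weights — selects exactly
one node per layer. A path's *frequency* is the product of the transition
probabilities along it; its *phenotype* is the ordered sequence of node
labels; the frequency of a phenotype is the summed frequency of the paths
that produce it.

One generation of the path evolution algorithm (PEA):

1. traverse two paths independently (with optional per-step
   uniform-exploration probability `gamma`);
2. evaluate both phenotypes under the reward function (the generation index
   is passed through, so environments may change over time);
3. the higher-reward path wins; its private edges (not shared with the
   loser) are multiplied by `(1 + lambda)`, the loser's private edges by
   `(1 − lambda)`, and every node whose outflow changed is renormalized.
   Shared edges are untouched, or punished like the loser's under the
   diversity-maintenance variant (`punish_shared`);
4. with probability `chi`, two-point crossover splices a weak edge from the
   losing path into the winning path and a second weak edge back;
5. every node on either traversed path mutates independently with
   probability `mu` (structural operators below);
6. edges whose weight sank below the removal cutoff are pruned, and nodes
   inactive for more than `tau` generations are removed (a layer's last
   node never is; unreachable or dead-end nodes are culled by cascade).

Selection therefore acts purely on transition probabilities: a winning
path's frequency grows multiplicatively, and because paths overlap, so do
parts of every path sharing its edges.

## Structural variation

A mutation event at node `g` (predecessor `p`, successor `s` on the
traversed path) takes one of two forms:

* **bypass creation** (probability `1 − attach_prob`): a new node `g'` in
  `g`'s layer receives a weak edge `p → g'` and a full-strength edge
  `g' → s`. Binary mutants flip the parent's label by default
  (`mutant_label`: copy/flip/random); continuous mutants draw a Gaussian
  around the parent value (s.d. `mutation_sd`), clipped to [−1, 1]. A
  label-copying mutant produces no new phenotype, so flipping is the
  default: a single mutation then yields new but correlated path
  phenotypes.
* **attachment** (probability `attach_prob`, default 2/3): the weak edge
  `p → h` instead connects to an *existing* node of the layer — creating a
  node is equivalent to connecting to and from existing material. Targets
  are biased to the opposite label (binary) or drawn with Gaussian-proximity
  weights in value (continuous), mirroring a topographic map in which
  nearby units carry nearby values. If `h` has no outflow it is completed
  as a clean bypass (`h → s` at weight 1); otherwise `h` grows one onward
  connection of its own, so the two-hop graft returns to the parent route
  part of the time and diverges into `h`'s own continuation otherwise —
  this is what recombines segments of coexisting routes.

Two capacity rules keep the network lean, both taken from the
spiking-network realization of the same algorithm: a per-node out-degree
cap (`max_out_degree`, default 3; the weakest edge is evicted on overflow)
and per-layer node caps. Creation at a full layer recycles the layer's
least-recently-active node. Without the out-degree cap, structural churn
floods outflows with weak edges until traversals deviate many times per
path and the selection signal drowns; without recycling, a full layer can
never again produce a cleanly rejoining variant and optimization stalls on
its last few loci.

Fresh weak edges are spliced in at exactly `omega` *post-normalization*
(the rest of the outflow is scaled by `1 − omega`), and the edge-removal
cutoff (`prune_threshold`, default `omega/10`) sits strictly below `omega`,
so a fresh variant survives a handful of lost tournaments rather than dying
on its first loss. Because the punishment is multiplicative and a branch is
only punished when traversed, a losing branch's weight decays like
`1/(2*lambda*t)`: the cutoff therefore directly sets how long outcompeted
routes persist (about `1/(2*lambda*cutoff)` generations).

Tied tournaments between structurally different paths resolve to a uniform
random winner by default (`tie_break="random"`), exactly as in the
steady-state tournament GA the engine parallels, where the strict
comparison's else-branch still infects. This gives selectively neutral
variation genuine drift; `tie_break="none"` (no change on equal rewards) is
available and leaves all weights invariant under a constant reward.

## Deterministic expected dynamics

On a fixed, enumerable network the one-generation expectation of the
stochastic update has a closed form: each unordered pair of distinct paths
`(i, j)` is drawn with probability `2 P(i) P(j)` and contributes its
post-tournament weight vector; the remaining mass (same path twice, or a
rank tie) contributes the unchanged weights. `dynamics.expected_step`
implements this mixture generically and reproduces the hand-derived
one-locus recurrence

    w' = (1 − 2w(1−w)) w + 2w(1−w) · w(1+λ) / (w(1+λ) + (1−w)(1−λ))

to rounding (the scalar form is also provided, since fixation is
asymptotically algebraic — the pair-draw probability vanishes with the
minority weight — and reaching |w − 1| < 1e−6 takes millions of cheap
iterations). Canonical small networks are provided for one locus, two loci
(two binary splits joined through a shared middle node, so path frequencies
are allele-weight products), and the fully connected two-locus ("XOR")
network with three free weights, where a selective reward ordering fixes
one path and a neutral ordering maintains the two complementary paths at
initial-condition-dependent frequencies — linkage disequilibrium from
weight change alone. Expected outflows are renormalized once per step:
pair masses sum to the square of the total path probability, so without the
projection a rounding excess doubles every generation.

## The microbial GA baseline

A minimal steady-state GA over non-overlapping genotypes: two distinct
random individuals meet; the loser is overwritten by the winner (wholly, or
per-locus with the infection probability in the recombination variant) and
then mutated per locus; ties still infect. One path generation costs two
evaluations and one microbial tournament costs two, so traces align on
evaluation count.

## Benchmarks

Counting ones; the 0/1 multiple knapsack with an overfill penalty (profit
if all capacities hold, else minus the total overfill), with a native text
dialect, an OR-Library reader, a seeded synthetic-instance generator and an
exhaustive oracle for n ≤ 24; the De Jong-style continuous functions
(sphere, Rosenbrock valley, quartic with switchable uniform noise,
Rastrigin) on their conventional domains, reached from node labels by an
affine map from [−1, 1]; the hierarchical if-and-only-if function (HIFF,
transfer [0,0]→0, [1,1]→1, else null; level multipliers 1, 2, 4, … from the
pair level, with the classic variant that also scores single bits behind a
flag); the 64-bit royal road (8 points per completed contiguous 8-bit
all-ones block); and the alternating counting-ones/zeros environment.

## Spiking realization

A 10×10 grid of regular-spiking Izhikevich neurons (a=0.02, b=0.2, c=−65,
d=8; 1 ms steps, two half-steps for the voltage, spikes clamped at 30 mV)
plus one start neuron realizes the same algorithm in biophysical currency.
Synapses carry 15–60 mV of delivered depolarization with a 1 ms delay;
winner-take-all competition lets each spike drive exactly one outgoing
synapse, weight-proportionally, so a trial's spike route is a sampled path.
Each second, the start neuron is depolarized at 10 ms; the phenotype is the
bits of the first ten distinct neurons spiking before the 50 ms reward
time, and fitness the count of ones. Reward is dopamine relative to a
running average (as printed, `avg ← 0.01·avg + 0.99·fitness`, which makes
the average track the previous trial and gates reward on strict
improvement): +0.5 DA per correct bit when above average, −0.5 per
incorrect readout slot when below. Eligibility traces (pair-based STDP,
20 ms window; potentiation on the delivering synapse when its target fires,
depression for post-before-delivery) decay with τ = 100 ms and dopamine
with τ = 50 ms — ten- and four-fold faster than the model this follows —
and weights change by `gain · trace · DA` per ms. Punishment may push a
weight below the 15 mV minimum, in which case the synapse is removed (only
the 60 mV ceiling clips); silent presynaptic neurons' outgoing weights also
decay linearly at 0.00002 mV/ms after one silent second, reaching the floor
from ~16.2 mV in about a minute. Structural plasticity: each spike carries
a 1% chance of a new synapse to an adjacent-row neuron of the next column,
whose target immediately grows one onward synapse likewise, so the graft is
a bypass one third of the time; at most three outputs per neuron and at
most 60 mV of total outflow (one synapse removed with probability inversely
proportional to weight on overflow). Neurons silent for a full minute flip
their phenotype bit. Background noise is an event-driven Poisson process of
suprathreshold kicks; the default per-neuron kick rate (0.06 Hz) puts the
realized firing rate, cascades included, near the low end of the intended
0.1–1 Hz band (`calibrate_background` measures it).

Two constants have no stated value and were calibrated once: the
weight-change gain (0.05 mV per unit trace×DA per ms, sized so one rewarded
trial moves the delivering synapse by ~1 mV; the cited model's weight scale
is 15× smaller, and an unscaled gain deletes or saturates a synapse in a
single trial) and the initial weight of structural synapses (30 mV: the
15 mV floor is exactly the unstable-equilibrium kick of an RS neuron at
rest and can never fire the target, and 20 mV synapses lose the WTA
competition too often to prove themselves).

The simulator fast-forwards quiet stretches in closed form (exponential
trace/dopamine decay, their product's weight-change integral, piecewise
linear silent decay, and membrane relaxation along the nullcline), stepping
millisecond-by-millisecond only around deliveries, stimulation, reward and
noise events; this is exact for the plasticity variables and a controlled
approximation for the membrane, and cuts a 5000-trial run to under two
minutes.

## Synthetic data and what passing tests show

All inputs are generated in code: networks from seeded initializers,
benchmark instances from seeded generators with brute-force optima, spike
activity from the simulator itself. The generators' defaults are the study
conditions of the experiments they reproduce (figure-caption parameter
sets, recorded verbatim in `experiments.RECIPES`). What they do not emulate
is any form of real neural data — the spiking model is a minimal
demonstration grid, not a fitted circuit — so passing tests certify the
algorithmic claims (selection, heredity, linkage, memory), not biological
realism.

## Problem sizes and known limitations

Test and acceptance runs use the caption-scale problems where those
complete in minutes (64-bit HIFF, 64-bit royal road, 20-dimensional
Rastrigin, the 10-bit spiking task) and documented scaled versions
elsewhere: the alternating-environment experiment runs at 32 bits with a
5,000-generation period (eight switches), preserving the full experiment's
geometry (layer cap 4, initialization far above the cap).

Known limitations, measured rather than assumed:

* On 64-bit HIFF the engine assembles the hierarchy reliably up to the
  16–32-bit levels but stalls one merge short of the global optimum within
  200,000 generations (best-so-far typically 100–145 of 192, still climbing
  slowly at 800,000). The final merge needs a complementary 32-layer route
  to stay both intact and reachable for tens of thousands of generations,
  and no faithful variant of the structural operators we tested achieves
  that at the stated parameters. The GA-side result (a microbial GA without
  crossover never finds the optimum) reproduces cleanly.
* On Rastrigin, the hill-climber-like parameter set does not end worse than
  the diversity-preserving set under this reconstruction: the
  diversity-preserving set's thousandfold-lower mutation rate dominates the
  comparison at the stated budget.
* The expected-dynamics operator is exact but enumerative: it is meant for
  the small canonical networks, not for evolved ones.
* Recurrent or variable-length topologies are out of scope.
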