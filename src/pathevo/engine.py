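"""The path evolution algorithm: tournament selection acting on paths.

One generation consists of: traverse two paths, evaluate their phenotypes,
multiplicatively strengthen the winner's private edges by ``(1 + lambda)`` and
weaken the loser's by ``(1 - lambda)`` (shared edges untouched, or punished
like the loser under the diversity-maintenance variant), renormalize the
outflow of every node whose outgoing weights changed, optionally cross the two
paths over, bypass-mutate the nodes of both traversed paths, and prune edges
that sank below the weak-weight threshold and nodes that have been inactive
for longer than their lifetime.

Selection therefore changes path *frequencies* (products of transition
probabilities), not copies of individuals: multiplicative growth without
template replication.
"""

from __future__ import annotations

import math
import random
import warnings
from collections import deque
from dataclasses import dataclass

from .network import BINARY, LayeredPathNetwork, init_network

__all__ = [
    "PEAConfig",
    "RunTrace",
    "select_winner",
    "tournament_update",
    "mutate_bypass",
    "crossover_two_point",
    "prune",
    "run_pea",
]

A_WINS = "A_wins"
B_WINS = "B_wins"
TIE = "tie_or_identical"


@dataclass
class PEAConfig:
    """All parameters of the path evolution algorithm.

    Names follow the figure captions: ``lam`` is the selection rate lambda,
    ``mu`` the per-node per-activation mutation probability, ``chi`` the
    crossover probability, ``tau`` the node-inactivity lifetime in
    generations, ``omega`` the weak initial edge weight (doubling as the
    strict pruning threshold), ``gamma`` the per-step uniform-exploration
    probability.  ``rho`` is carried for caption compatibility but has no
    defined meaning and is unused (a warning is raised if nonzero).
    """

    N: int = 1
    L: int = 10
    lam: float = 0.1
    mu: float = 0.0
    chi: float = 0.0
    tau: int = 200
    omega: float = 0.01
    gamma: float = 0.0
    rho: float = 0.0
    max_nodes_per_layer: int = 1000
    punish_shared: bool = False
    minimize: bool = False
    generations: int = 1000
    seed: int = 0
    scheme: str = BINARY
    mutation_sd: float = 0.1
    mutant_label: str = "flip"  # copy | flip | random (binary scheme)
    attach_prob: float = 2.0 / 3.0  # share of mutations that re-route into
    # existing layer material instead of creating a bypass node
    max_out_degree: int | None = 3  # per-node outgoing-edge cap enforced by
    # structural operators (weakest edge evicted), keeping outflows lean
    prune_threshold: float | None = None  # strict edge-removal cutoff;
    # None -> omega / 10.  A fresh mutant edge starts at omega, so a cutoff
    # below omega lets unfavorable variants persist through a few lost
    # tournaments instead of dying on their first loss.
    tie_break: str = "random"  # random: tied tournaments between
    # structurally different paths still resolve (uniformly) to a winner —
    # the steady-state tournament convention, giving neutral variation
    # genuine drift; none: ties change nothing
    log_every: int = 1
    prune_every: int = 25
    stop_at_target: bool = False

    @property
    def edge_cutoff(self) -> float:
        """Effective strict edge-removal threshold."""
        return (self.omega / 10.0 if self.prune_threshold is None
                else self.prune_threshold)

    def __post_init__(self):
        for name in ("mu", "chi", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lam must lie in (0, 1), got {self.lam}")
        if not 0.0 < self.omega < 1.0:
            raise ValueError(f"omega must lie in (0, 1), got {self.omega}")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.N < 1 or self.L < 1:
            raise ValueError("N and L must be >= 1")
        if self.mutant_label not in ("copy", "flip", "random"):
            raise ValueError(f"unknown mutant_label {self.mutant_label!r}")
        if self.tie_break not in ("random", "none"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.rho != 0.0:
            warnings.warn("rho has no defined meaning and is ignored",
                          stacklevel=2)


class RunTrace:
    """Per-generation record of a PEA (or GA) run.

    ``best`` is best-so-far reward (monotone under a fixed objective);
    ``phenotype_diversity`` estimates the number of distinct phenotypes by
    counting distinct phenotypes among the most recently traversed paths.
    """

    def __init__(self, evaluations_per_generation: int = 2):
        self.generation: list[int] = []
        self.reward_a: list[float] = []
        self.reward_b: list[float] = []
        self.best: list[float] = []
        self.n_nodes: list[int] = []
        self.n_edges: list[int] = []
        self.phenotype_diversity: list[int] = []
        self.evaluations_per_generation = evaluations_per_generation
        self.first_hit_generation: int | None = None
        self.mutations = 0
        self.mutation_skips = 0
        self.crossovers = 0

    def log(self, gen, ra, rb, best, n_nodes, n_edges, diversity):
        self.generation.append(gen)
        self.reward_a.append(ra)
        self.reward_b.append(rb)
        self.best.append(best)
        self.n_nodes.append(n_nodes)
        self.n_edges.append(n_edges)
        self.phenotype_diversity.append(diversity)

    @property
    def final_best(self) -> float:
        return self.best[-1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "generation": self.generation,
            "evaluations": [g * self.evaluations_per_generation
                            for g in self.generation],
            "reward_a": self.reward_a,
            "reward_b": self.reward_b,
            "best": self.best,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "phenotype_diversity": self.phenotype_diversity,
        })

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, path: str | None = None):
        """Best-so-far reward and network size over evaluations (requires
        matplotlib)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
        ax1.plot(df["evaluations"], df["best"], lw=1.2)
        ax1.set_ylabel("best reward")
        ax2.plot(df["evaluations"], df["n_nodes"], lw=1.0, label="nodes")
        ax2.plot(df["evaluations"], df["n_edges"], lw=1.0, label="edges")
        ax2.set_xlabel("fitness evaluations")
        ax2.set_ylabel("network size")
        ax2.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def select_winner(reward_a: float, reward_b: float, minimize: bool = False) -> str:
    """Tournament outcome for two rewards; ties yield no winner."""
    if math.isnan(reward_a) or math.isnan(reward_b):
        raise ValueError("NaN reward")
    if reward_a == reward_b:
        return TIE
    if (reward_a < reward_b) == minimize:
        return A_WINS
    return B_WINS


def _edge_set(path: tuple[int, ...]) -> set[tuple[int, int]]:
    return set(zip(path, path[1:]))


def tournament_update(net: LayeredPathNetwork, winner: tuple[int, ...],
                      loser: tuple[int, ...], lam: float,
                      punish_shared: bool = False) -> set[int]:
    """Multiplicative winner/loser weight update followed by renormalization.

    Winner-only edges are multiplied by ``(1 + lam)``, loser-only edges by
    ``(1 - lam)``; edges shared by both paths are left untouched unless
    ``punish_shared`` (then treated like the loser's).  Only nodes whose
    outgoing set changed are renormalized; their ids are returned.  Identical
    edge sets are a no-op.
    """
    w_edges = _edge_set(winner)
    l_edges = _edge_set(loser)
    if w_edges == l_edges:
        return set()
    touched: set[int] = set()
    for u, v in w_edges - l_edges:
        net.set_edge_weight(u, v, net.edge_weight(u, v) * (1.0 + lam))
        touched.add(u)
    losing = (l_edges - w_edges) | (w_edges & l_edges) if punish_shared \
        else l_edges - w_edges
    for u, v in losing:
        net.set_edge_weight(u, v, net.edge_weight(u, v) * (1.0 - lam))
        touched.add(u)
    for u in touched:
        net.normalize(u)
    return touched


def _splice_edge(net: LayeredPathNetwork, u: int, v: int, omega: float,
                 max_out: int | None = None) -> None:
    """Give edge ``u -> v`` weight at least ``omega`` *post-normalization*,
    scaling the rest of u's outflow proportionally.  A fresh weak edge thus
    sits exactly at the pruning threshold and survives the strict-< prune.

    When ``max_out`` is set and the splice would exceed it, the weakest of
    u's other outgoing edges is evicted first (the outflow stays lean, as
    under the spiking realization's output cap)."""
    ts, ws = net.out_t[u], net.out_w[u]
    if max_out is not None and v not in ts and len(ts) >= max_out:
        k = min(range(len(ws)), key=ws.__getitem__)
        victim = ts[k]
        net.remove_edge(u, victim)
        if net.out_t[u]:
            net.normalize(u)
        ts, ws = net.out_t[u], net.out_w[u]
    if v in ts:
        i = ts.index(v)
        if ws[i] >= omega:
            return
        cur = ws[i]
        rest = sum(ws) - cur
        if rest <= 0:
            ws[i] = 1.0
            return
        scale = (1.0 - omega) / rest
        for k in range(len(ws)):
            ws[k] *= scale
        ws[i] = omega
        return
    if not ts:
        net.add_edge(u, v, 1.0)
        return
    s = sum(ws)
    scale = (1.0 - omega) / s
    for k in range(len(ws)):
        ws[k] *= scale
    net.add_edge(u, v, omega)


def _opposite_label_nodes(net: LayeredPathNetwork, layer: int,
                          g: int) -> list[int]:
    """Attachment candidates in a layer: nodes carrying the opposite binary
    label (alternative alleles), falling back to any other node (single-label
    layers)."""
    nodes = net.layers[layer]
    if net.scheme == BINARY:
        opp = 1 - net.label[g]
        cands = [n for n in nodes if net.label[n] == opp]
        if cands:
            return cands
    return [n for n in nodes if n != g]


def _pick_attach_target(net: LayeredPathNetwork, layer: int, g: int,
                        rng: random.Random, sd: float) -> int | None:
    """Attachment target for a mutation at node ``g``.

    Binary scheme: uniform over opposite-label nodes (any other node if the
    layer is single-label).  Continuous scheme: a nearby node, weighted by a
    Gaussian (s.d. ``sd``) of the distance between node values.
    """
    if net.scheme == BINARY:
        cands = _opposite_label_nodes(net, layer, g)
        if not cands:
            return None
        return cands[int(rng.random() * len(cands))]
    cands = [n for n in net.layers[layer] if n != g]
    if not cands:
        return None
    ref = net.label[g]
    weights = [math.exp(-0.5 * ((net.label[n] - ref) / sd) ** 2)
               for n in cands]
    total = sum(weights)
    if total <= 0.0:
        return cands[int(rng.random() * len(cands))]
    r = rng.random() * total
    acc = 0.0
    for n, w in zip(cands, weights):
        acc += w
        if r < acc:
            return n
    return cands[-1]


#: fraction of mutation events that attach to an existing node of the layer
#: (divergent re-routing) rather than creating a fresh bypass node; matches
#: the 2/3 divergent share of the spiking realization's structural rule
ATTACH_PROB = 2.0 / 3.0


def mutate_bypass(net: LayeredPathNetwork, path: tuple[int, ...], mu: float,
                  omega: float, rng: random.Random, generation: int = 0,
                  mutation_sd: float = 0.1, mutant_label: str = "flip",
                  attach_prob: float = ATTACH_PROB,
                  max_out: int | None = 3,
                  ) -> tuple[int, int, set[int]]:
    """Structural mutation of the activated nodes of one traversed path.

    Each node ``g`` at phenotype layers 1..L mutates independently with
    probability ``mu``.  A mutation event takes one of two forms:

    * *bypass* (probability ``1 - attach_prob``, layer below its node cap):
      a new node in g's layer receives a weak edge from g's predecessor on
      the path and a full-strength edge to g's successor — an alternative
      single-node detour whose phenotype is correlated with the parent
      path's.  Binary mutants take their label from ``mutant_label`` (copy
      of the parent, flipped, or a fresh coin); continuous mutants draw a
      Gaussian around the parent value (s.d. ``mutation_sd``), clipped to
      [-1, 1].
    * *attachment* (probability ``attach_prob``, or always once the layer is
      at its cap): the weak edge from g's predecessor instead connects to an
      existing other node of the layer — creating a new node is equivalent
      to connecting to previously existing material.  If that node has no
      outflow it is completed as a bypass (full-strength edge to g's
      successor); if it already flows onward the route diverges into the
      attached node's own continuation, recombining path segments.

    Returns ``(mutations, skips, touched_nodes)``; events with no available
    material (capped layer with no other node) are skipped and counted.
    """
    applied = skipped = 0
    touched: set[int] = set()
    L = net.L
    for i in range(1, L + 1):
        if rng.random() >= mu:
            continue
        g = path[i]
        pred = path[i - 1]
        succ = path[i + 1] if i < L else None
        layer_nodes = net.layers[i]
        at_cap = len(layer_nodes) >= net.max_nodes_per_layer
        attach = rng.random() < attach_prob
        if not attach and at_cap:
            # node creation at a full layer recycles the most stale node:
            # "creating" is connecting to and from existing unused material
            victims = sorted((n for n in layer_nodes
                              if n != g and n not in path),
                             key=net.last_active.get)
            recycled = False
            for v in victims:
                if any(len(net.out_t[p]) <= 1 for p in net.preds[v]):
                    continue
                net.remove_node(v)
                recycled = True
                break
            if not recycled:
                attach = True   # no recyclable material: divert the event
            at_cap = len(net.layers[i]) >= net.max_nodes_per_layer
        if attach:
            h = _pick_attach_target(net, i, g, rng, mutation_sd)
            if h is None:
                if at_cap:
                    skipped += 1
                    continue
                attach = False   # no material to attach to: create instead
            else:
                _splice_edge(net, pred, h, omega, max_out)
                touched.add(pred)
                if succ is not None:
                    if not net.out_t[h]:
                        net.add_edge(h, succ, 1.0)
                    else:
                        # second hop: the attached node grows one onward
                        # connection of its own, again toward an
                        # alternative-label node of the next layer (the
                        # path's successor as fallback), so the graft either
                        # rejoins the parent route or extends a divergent
                        # alternative segment
                        k = _pick_attach_target(net, i + 1, path[i + 1],
                                                rng, mutation_sd)
                        if k is None:
                            k = path[i + 1]
                        _splice_edge(net, h, k, omega, max_out)
                        touched.add(h)
                net.last_active[h] = generation
                applied += 1
                continue
        if net.scheme == BINARY:
            if mutant_label == "copy":
                lab = net.label[g]
            elif mutant_label == "flip":
                lab = 1 - net.label[g]
            else:
                lab = rng.randint(0, 1)
        else:
            lab = min(1.0, max(-1.0, rng.gauss(net.label[g], mutation_sd)))
        g2 = net.add_node(i, lab, generation)
        _splice_edge(net, pred, g2, omega, max_out)
        touched.add(pred)
        if succ is not None:
            net.add_edge(g2, succ, 1.0)
        applied += 1
    return applied, skipped, touched


def crossover_two_point(net: LayeredPathNetwork, winner: tuple[int, ...],
                        loser: tuple[int, ...], chi: float, omega: float,
                        rng: random.Random,
                        max_out: int | None = 3) -> tuple[bool, set[int]]:
    """Two-point crossover between a winning and a losing path.

    With probability ``chi``, a weak edge is spliced from a random layer of
    the losing path to the next layer of the winning path, and a second weak
    edge from a later random layer of the winning path back to the losing
    path, creating a hybrid route.  Pre-existing edges are raised to at least
    the weak weight rather than duplicated.  Returns (applied, touched nodes).
    """
    L = net.L
    if L < 3:
        warnings.warn("crossover skipped: path length < 3", stacklevel=2)
        return False, set()
    if rng.random() >= chi:
        return False, set()
    i = rng.randint(0, L - 2)
    j = rng.randint(i + 1, L - 1)
    touched = set()
    _splice_edge(net, loser[i], winner[i + 1], omega, max_out)
    touched.add(loser[i])
    _splice_edge(net, winner[j], loser[j + 1], omega, max_out)
    touched.add(winner[j])
    return True, touched


def _prune_edges_of(net: LayeredPathNetwork, nodes, omega: float) -> int:
    """Remove sub-threshold edges (strictly below omega) from the given
    nodes' outflows, never stripping a node's last edge; renormalize."""
    removed = 0
    for u in nodes:
        ws = net.out_w.get(u)
        if ws is None or len(ws) < 2:
            continue
        if min(ws) >= omega:
            continue
        ts = net.out_t[u]
        keep_i = max(range(len(ws)), key=ws.__getitem__)
        doomed = [v for k, (v, w) in enumerate(zip(ts, ws))
                  if w < omega and k != keep_i]
        for v in doomed:
            net.remove_edge(u, v)
            removed += 1
        if doomed:
            net.normalize(u)
    return removed


def prune(net: LayeredPathNetwork, generation: int, tau: int,
          omega: float) -> tuple[int, int]:
    """Full structural prune: drop sub-threshold edges and stale nodes.

    Edges with weight strictly below ``omega`` are removed (keeping every
    node's strongest edge).  Non-start nodes inactive for more than ``tau``
    generations are removed, as are nodes left without inflow or outflow,
    cascading until stable.  A layer's sole remaining node is never removed,
    nor is a node whose removal would strip a surviving predecessor's last
    outgoing edge.  Returns (nodes_removed, edges_removed).
    """
    edges_removed = _prune_edges_of(net, list(net.out_t), omega)
    nodes_removed = 0
    changed = True
    while changed:
        changed = False
        for n in list(net.layer_of):
            if n == net.start or n not in net.layer_of:
                continue
            layer = net.layer_of[n]
            stale = generation - net.last_active[n] > tau
            orphan = not net.preds[n]
            dead_end = layer < net.L and not net.out_t[n]
            if not (stale or orphan or dead_end):
                continue
            if len(net.layers[layer]) <= 1:
                continue
            if any(len(net.out_t[p]) <= 1 for p in net.preds[n]):
                continue
            net.remove_node(n)
            nodes_removed += 1
            changed = True
    return nodes_removed, edges_removed


def run_pea(config: PEAConfig, fitness) -> RunTrace:
    """Run the path evolution algorithm; fully reproducible from the seed.

    ``fitness`` maps ``(phenotype, generation) -> reward`` and may expose
    ``minimize``, ``scheme`` and ``optimum`` attributes (see
    :mod:`pathevo.benchmarks`).  If ``config.stop_at_target`` is set and the
    fitness declares an ``optimum``, the run stops at the first generation a
    traversed phenotype attains it (recorded in
    ``trace.first_hit_generation`` either way).
    """
    scheme = getattr(fitness, "scheme", config.scheme)
    minimize = getattr(fitness, "minimize", config.minimize)
    optimum = getattr(fitness, "optimum", None)
    rng = random.Random(config.seed)
    net = init_network(config.N, config.L, scheme,
                       config.max_nodes_per_layer, rng)
    trace = RunTrace()
    recent: deque = deque(maxlen=200)
    recent_set: dict = {}
    best = math.inf if minimize else -math.inf
    better = min if minimize else max
    gen = 0
    for gen in range(config.generations):
        path_a = net.traverse(config.gamma, rng)
        path_b = net.traverse(config.gamma, rng)
        for n in path_a:
            net.last_active[n] = gen
        for n in path_b:
            net.last_active[n] = gen
        ph_a = net.phenotype_of(path_a)
        ph_b = net.phenotype_of(path_b)
        r_a = fitness(ph_a, gen)
        r_b = fitness(ph_b, gen)
        outcome = TIE if path_a == path_b else select_winner(r_a, r_b, minimize)
        if outcome == TIE and config.tie_break == "random" \
                and path_a != path_b:
            outcome = A_WINS if rng.random() < 0.5 else B_WINS
        touched: set[int] = set()
        if outcome != TIE:
            win, lose = ((path_a, path_b) if outcome == A_WINS
                         else (path_b, path_a))
            touched |= tournament_update(net, win, lose, config.lam,
                                         config.punish_shared)
            if config.chi > 0.0 and config.L >= 3:
                applied, t2 = crossover_two_point(net, win, lose, config.chi,
                                                  config.omega, rng,
                                                  config.max_out_degree)
                if applied:
                    trace.crossovers += 1
                    touched |= t2
        for p in (path_a, path_b):
            if config.mu > 0.0:
                napp, nskip, t3 = mutate_bypass(
                    net, p, config.mu, config.omega, rng, gen,
                    config.mutation_sd, config.mutant_label,
                    config.attach_prob, config.max_out_degree)
                trace.mutations += napp
                trace.mutation_skips += nskip
                touched |= t3
        best = better(best, r_a, r_b)
        if optimum is not None and trace.first_hit_generation is None \
                and (r_a == optimum or r_b == optimum):
            trace.first_hit_generation = gen
        # diversity estimate over the most recent traversed phenotypes
        for ph in (ph_a, ph_b):
            if len(recent) == recent.maxlen:
                old = recent.popleft()
                recent_set[old] -= 1
                if not recent_set[old]:
                    del recent_set[old]
            recent.append(ph)
            recent_set[ph] = recent_set.get(ph, 0) + 1
        if touched:
            _prune_edges_of(net, touched, config.edge_cutoff)
        if gen % config.prune_every == 0:
            prune(net, gen, config.tau, config.edge_cutoff)
        if gen % config.log_every == 0 or gen == config.generations - 1 \
                or (config.stop_at_target and best == optimum):
            trace.log(gen, r_a, r_b, best, net.n_nodes, net.n_edges,
                      len(recent_set))
        if config.stop_at_target and optimum is not None and best == optimum:
            break
    trace.network = net
    return trace
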