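"""Exact expected dynamics of path selection on small fixed networks.

The stochastic tournament update has a closed one-generation expectation on
any enumerable network: each unordered pair of distinct paths (i, j) is drawn
with probability 2 P(i) P(j), in which case the winner/loser multiplicative
update and renormalization apply, and with the remaining probability mass
(same path twice, or a tie in rank) nothing changes.  Iterating the
expectation gives the deterministic allele-frequency recurrences: fixation of
the fitter allele at one locus, simultaneous fixation at two loci, and
linkage disequilibrium on the XOR-style fully connected two-locus network
(where a neutral fitness ordering maintains the two complementary paths at
initial-condition-dependent frequencies).

Allele weights live on a fixed topology; only edge weights evolve here
(mutation and structural change are the stochastic engine's business).
"""

from __future__ import annotations

import numpy as np

from .engine import tournament_update
from .network import BINARY, LayeredPathNetwork

__all__ = [
    "FIXATION_TOL",
    "expected_step",
    "one_locus_network",
    "one_locus_trajectory",
    "two_locus_network",
    "two_locus_trajectory",
    "xor_network",
    "xor_model_trajectory",
]

#: |w - 1| below this declares fixation
FIXATION_TOL = 1e-6


def _rank_of(ordering, phenotype) -> float:
    if callable(ordering):
        return ordering(phenotype)
    return ordering[phenotype]


def expected_step(net: LayeredPathNetwork, ordering, lam: float,
                  punish_shared: bool = False) -> dict[tuple[int, int], float]:
    """One exact expected generation; updates ``net`` in place.

    ``ordering`` maps phenotypes to rank values (higher rank wins; callable
    or mapping, total over the network's phenotypes).  Returns the new edge
    weights as a ``{(u, v): w}`` dict.  The expectation mixes, over all path
    pairs, the weight vector each pair outcome produces; since every outcome
    is normalized, the expected outflows remain normalized.
    """
    paths = net.enumerate_paths()
    ranks = [_rank_of(ordering, net.phenotype_of(p)) for p, _ in paths]

    def snapshot() -> dict[tuple[int, int], float]:
        return {(u, v): w for u in net.out_t
                for v, w in zip(net.out_t[u], net.out_w[u])}

    def restore(ws: dict[tuple[int, int], float]) -> None:
        for (u, v), w in ws.items():
            net.set_edge_weight(u, v, w)

    base = snapshot()
    expect = {e: 0.0 for e in base}
    no_change_mass = sum(p * p for _, p in paths)
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            (pi, qi), (pj, qj) = paths[i], paths[j]
            mass = 2.0 * qi * qj
            if mass == 0.0:
                continue
            if ranks[i] == ranks[j]:
                no_change_mass += mass
                continue
            win, lose = (pi, pj) if ranks[i] > ranks[j] else (pj, pi)
            touched = tournament_update(net, win, lose, lam, punish_shared)
            if not touched:
                no_change_mass += mass
                restore(base)
                continue
            after = snapshot()
            for e in expect:
                expect[e] += mass * after[e]
            restore(base)
    for e in expect:
        expect[e] += no_change_mass * base[e]
    restore(expect)
    # guard against compounding rounding drift: pair masses sum to the square
    # of the total path probability, so any excess doubles per generation
    # unless outflows are snapped back onto the simplex
    for u in net.out_t:
        if net.out_t[u]:
            net.normalize(u)
    return snapshot()


# ----------------------------------------------------------------------
# canonical small networks
# ----------------------------------------------------------------------
def one_locus_network(w1: float) -> tuple[LayeredPathNetwork, tuple, tuple]:
    """One locus, two alleles: start fans out to a label-1 node (weight w1)
    and a label-0 node (weight 1 - w1).  Returns (net, allele1_edge,
    allele0_edge)."""
    net = LayeredPathNetwork(1, BINARY)
    a = net.add_node(1, 1)
    b = net.add_node(1, 0)
    _add_split(net, net.start, a, b, w1)
    return net, (net.start, a), (net.start, b)


def _add_split(net, u, hi, lo, w):
    """Two-way outflow with weights (w, 1-w); boundary weights collapse to a
    single absorbing edge."""
    if w > 0.0:
        net.add_edge(u, hi, w)
    if w < 1.0:
        net.add_edge(u, lo, 1.0 - w)


def one_locus_trajectory(w1_0: float, lam: float, steps: int,
                         winner_label: int = 1) -> np.ndarray:
    """Deterministic trajectory of the fitter allele's weight w1.

    The allele labelled ``winner_label`` carries the higher reward; from any
    interior start its weight increases monotonically to fixation
    (|w1 - 1| < FIXATION_TOL) and the other allele goes extinct.
    """
    if not 0.0 < w1_0 < 1.0:
        raise ValueError("w1_0 must lie in (0, 1)")
    net, e1, _ = one_locus_network(w1_0)
    ordering = {(1,): 1.0, (0,): 0.0} if winner_label == 1 else \
        {(1,): 0.0, (0,): 1.0}
    traj = [w1_0]
    for _ in range(steps):
        ws = expected_step(net, ordering, lam)
        traj.append(ws[e1])
        if abs(traj[-1] - 1.0) < FIXATION_TOL:
            break
    return np.asarray(traj)


def one_locus_recurrence(w: float, lam: float) -> float:
    """Algebraic one-generation recurrence for the fitter allele's weight:
    with probability 2 w (1 - w) a mixed pair is drawn and the weight moves
    to its renormalized post-tournament value, otherwise it is unchanged.
    This is the scalar specialization of :func:`expected_step` on the
    one-locus network (the two agree to rounding; see the tests)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    p_pair = 2.0 * w * (1.0 - w)
    updated = w * (1.0 + lam) / (w * (1.0 + lam) + (1.0 - w) * (1.0 - lam))
    return (1.0 - p_pair) * w + p_pair * updated


def one_locus_fixation_time(w0: float, lam: float, tol: float = FIXATION_TOL,
                            max_steps: int = 50_000_000) -> tuple[int, float]:
    """Generations until |w - 1| < tol under the one-locus recurrence.

    Fixation is asymptotically algebraic (the pair-draw probability vanishes
    with the minority weight), so tight tolerances take millions of cheap
    scalar iterations; returns ``(steps, w_final)``.
    """
    w = w0
    for t in range(1, max_steps + 1):
        w = one_locus_recurrence(w, lam)
        if abs(w - 1.0) < tol:
            return t, w
    raise RuntimeError(f"no fixation within {max_steps} steps (w={w})")


def two_locus_network(w1: float, w3: float
                      ) -> tuple[LayeredPathNetwork, dict]:
    """Two loci with two alleles each, realized as two binary splits joined
    through a shared middle node (label 0), so that path frequencies are the
    allele-weight products P(A) = w1*w3 etc.  Locus 1 is phenotype position
    0, locus 2 is position 2; the favored alleles (label 0) carry weights
    ``w1`` and ``w3``.
    """
    net = LayeredPathNetwork(3, BINARY)
    a1 = net.add_node(1, 0)
    a2 = net.add_node(1, 1)
    m = net.add_node(2, 0)
    b1 = net.add_node(3, 0)
    b2 = net.add_node(3, 1)
    _add_split(net, net.start, a1, a2, w1)
    net.add_edge(a1, m, 1.0)
    if w1 < 1.0:
        net.add_edge(a2, m, 1.0)
    _add_split(net, m, b1, b2, w3)
    edges = {"w1": (net.start, a1), "w3": (m, b1)}
    return net, edges


def two_locus_trajectory(w1_0: float, w3_0: float, lam: float, steps: int
                         ) -> dict[str, np.ndarray]:
    """Expected dynamics at two loci under minimize-count-of-ones ranking.

    Returns arrays ``w1``, ``w3`` and the four path frequencies ``A`` (both
    favored alleles), ``B``, ``C``, ``D`` (neither).  Both favored weights
    are non-decreasing and reach fixation jointly with path A.
    """
    for v in (w1_0, w3_0):
        if not 0.0 <= v <= 1.0:
            raise ValueError("initial weights must lie in [0, 1]")
    net, edges = two_locus_network(w1_0, w3_0)
    ordering = lambda ph: -float(sum(ph))     # minimize number of ones
    w1s, w3s = [w1_0], [w3_0]
    for _ in range(steps):
        ws = expected_step(net, ordering, lam)
        w1s.append(ws[edges["w1"]])
        w3s.append(ws[edges["w3"]])
        if abs(w1s[-1] - 1.0) < FIXATION_TOL and \
                abs(w3s[-1] - 1.0) < FIXATION_TOL:
            break
    w1a, w3a = np.asarray(w1s), np.asarray(w3s)
    return {"w1": w1a, "w3": w3a,
            "A": w1a * w3a, "B": w1a * (1 - w3a),
            "C": (1 - w1a) * w3a, "D": (1 - w1a) * (1 - w3a)}


def two_locus_vector_field(n: int = 21, lam: float = 0.1,
                           lo: float = 0.045, hi: float = 0.955
                           ) -> dict[str, np.ndarray]:
    """One-generation expected displacement (dw1, dw3) on an n x n grid of
    interior initial conditions.  Both components are non-negative
    everywhere: joint fixation of the favored alleles is inevitable from any
    starting point."""
    grid = np.linspace(lo, hi, n)
    dw1 = np.empty((n, n))
    dw3 = np.empty((n, n))
    ordering = lambda ph: -float(sum(ph))
    for i, w1 in enumerate(grid):
        for j, w3 in enumerate(grid):
            net, edges = two_locus_network(w1, w3)
            ws = expected_step(net, ordering, lam)
            dw1[i, j] = ws[edges["w1"]] - w1
            dw3[i, j] = ws[edges["w3"]] - w3
    return {"w1": grid, "w3": grid, "dw1": dw1, "dw3": dw3}


def xor_network(x: float, y: float, z: float
                ) -> tuple[LayeredPathNetwork, dict]:
    """Fully connected two-locus network with three free parameters.

    Start splits x / (1-x) to a label-1 and a label-0 node; each splits
    again (y, 1-y) and (z, 1-z) onto the shared second-layer label-1 /
    label-0 nodes.  Paths: A = "11" (freq x*y), B = "10" (x*(1-y)),
    C = "01" ((1-x)*z), D = "00" ((1-x)*(1-z)).
    """
    net = LayeredPathNetwork(2, BINARY)
    u1 = net.add_node(1, 1)
    u0 = net.add_node(1, 0)
    v1 = net.add_node(2, 1)
    v0 = net.add_node(2, 0)
    net.add_edge(net.start, u1, x)
    net.add_edge(net.start, u0, 1.0 - x)
    net.add_edge(u1, v1, y)
    net.add_edge(u1, v0, 1.0 - y)
    net.add_edge(u0, v1, z)
    net.add_edge(u0, v0, 1.0 - z)
    edges = {"x": (net.start, u1), "y": (u1, v1), "z": (u0, v1)}
    return net, edges


SELECTIVE_ORDERING = {(1, 0): 2.0, (0, 1): 1.0, (1, 1): 0.0, (0, 0): 0.0}
NEUTRAL_ORDERING = {(1, 0): 1.0, (0, 1): 1.0, (1, 1): 0.0, (0, 0): 0.0}


def xor_model_trajectory(x0: float, y0: float, z0: float, ordering,
                         lam: float, steps: int) -> dict[str, np.ndarray]:
    """Expected dynamics of the three weights and four path frequencies.

    Under the selective ordering 10 > 01 > 11 = 00, path B ("10") fixates;
    under the neutral ordering 10 = 01 > 11 = 00, paths B and C coexist at
    levels set by the initial weight x0 while A and D go extinct — linkage
    disequilibrium maintained by weight change alone.
    """
    net, edges = xor_network(x0, y0, z0)
    xs, ys, zs = [x0], [y0], [z0]
    for _ in range(steps):
        ws = expected_step(net, ordering, lam)
        xs.append(ws[edges["x"]])
        ys.append(ws[edges["y"]])
        zs.append(ws[edges["z"]])
    x, y, z = (np.asarray(a) for a in (xs, ys, zs))
    return {"x": x, "y": y, "z": z,
            "A": x * y, "B": x * (1 - y),
            "C": (1 - x) * z, "D": (1 - x) * (1 - z)}
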