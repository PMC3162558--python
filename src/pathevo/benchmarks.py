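"""Benchmark fitness functions, knapsack instance I/O and brute-force oracles.

Covers the combinatorial problems (counting ones, multiple knapsack with an
overfill penalty, HIFF, royal road, the alternating counting-ones/zeros
memory task) and the De Jong-style continuous functions (sphere, Rosenbrock
valley, quartic with noise, Rastrigin), together with a reader for a simple
native knapsack text dialect and the OR-Library multiple-knapsack sequence,
a seeded synthetic-instance generator, and exhaustive oracles small enough
to brute-force.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network import BINARY, CONTINUOUS

__all__ = [
    "FitnessFunction",
    "KnapsackInstance",
    "knapsack_fitness",
    "read_knapsack",
    "write_knapsack",
    "generate_knapsack",
    "brute_force_knapsack",
    "sphere",
    "rosenbrock",
    "quartic_noise",
    "rastrigin",
    "decode_continuous",
    "hiff",
    "royal_road",
    "alternating_count",
    "counting_ones_fitness",
    "knapsack_fn",
    "hiff_fitness",
    "royal_road_fitness",
    "alternating_fitness",
    "sphere_fitness",
    "rosenbrock_fitness",
    "quartic_fitness",
    "rastrigin_fitness",
    "DE_JONG_BOUNDS",
]


@dataclass
class FitnessFunction:
    """A reward function over phenotypes (or GA genotypes).

    ``evaluator`` maps ``(sequence, generation) -> float``; the generation
    index supports time-varying environments.  ``minimize`` tags the
    optimization sense, ``scheme`` the expected label kind, ``bounds`` the
    decoded domain for continuous problems, and ``optimum`` the known optimal
    reward where one exists (used for first-hit detection and early stop).
    """

    name: str
    scheme: str
    evaluator: Callable[[Sequence, int], float]
    minimize: bool = False
    bounds: tuple[float, float] | None = None
    optimum: float | None = None

    def __call__(self, phenotype: Sequence, generation: int = 0) -> float:
        return self.evaluator(phenotype, generation)


# ----------------------------------------------------------------------
# multiple knapsack
# ----------------------------------------------------------------------
@dataclass
class KnapsackInstance:
    """0/1 multiple-knapsack instance: one profit per object, one weight per
    object per knapsack, one capacity per knapsack."""

    profits: tuple[float, ...]
    weights: tuple[tuple[float, ...], ...]  # m rows of n weights
    capacities: tuple[float, ...]
    name: str = "knapsack"
    known_optimum: float | None = None

    def __post_init__(self):
        self.profits = tuple(float(p) for p in self.profits)
        self.weights = tuple(tuple(float(w) for w in row)
                             for row in self.weights)
        self.capacities = tuple(float(c) for c in self.capacities)
        n, m = self.n, self.m
        if len(self.capacities) != m:
            raise ValueError("one capacity per knapsack required")
        for row in self.weights:
            if len(row) != n:
                raise ValueError("each weight row must have n entries")
        if any(p < 0 for p in self.profits) or \
                any(w < 0 for row in self.weights for w in row) or \
                any(c < 0 for c in self.capacities):
            raise ValueError("profits, weights and capacities must be >= 0")

    @property
    def n(self) -> int:
        return len(self.profits)

    @property
    def m(self) -> int:
        return len(self.weights)


def knapsack_fitness(x: Sequence[int], inst: KnapsackInstance) -> float:
    """Profit of the packing if feasible, else minus the total overfill.

    The overfill penalty sums, over knapsacks, the amount by which each
    capacity is exceeded, and is returned negated so any infeasible packing
    scores below any feasible one.
    """
    if len(x) != inst.n:
        raise ValueError(f"expected {inst.n} items, got {len(x)}")
    overfill = 0.0
    for row, cap in zip(inst.weights, inst.capacities):
        load = sum(w for w, xi in zip(row, x) if xi)
        if load > cap:
            overfill += load - cap
    if overfill > 0.0:
        return -overfill
    return sum(p for p, xi in zip(inst.profits, x) if xi)


def write_knapsack(inst: KnapsackInstance, path: str) -> None:
    """Write the native structured-text dialect (keys n, m, profits,
    one weights row per knapsack, capacities)."""
    lines = [f"n {inst.n}", f"m {inst.m}",
             "profits " + " ".join(f"{p:g}" for p in inst.profits)]
    for row in inst.weights:
        lines.append("weights " + " ".join(f"{w:g}" for w in row))
    lines.append("capacities " + " ".join(f"{c:g}" for c in inst.capacities))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class KnapsackParseError(ValueError):
    pass


def _parse_native(text: str) -> KnapsackInstance:
    n = m = None
    profits = None
    weights = []
    capacities = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rest = line.partition(" ")
        try:
            if key == "n":
                n = int(rest)
            elif key == "m":
                m = int(rest)
            elif key == "profits":
                profits = [float(t) for t in rest.split()]
            elif key == "weights":
                weights.append([float(t) for t in rest.split()])
            elif key == "capacities":
                capacities = [float(t) for t in rest.split()]
            else:
                raise KnapsackParseError(f"line {lineno}: unknown key {key!r}")
        except ValueError as exc:
            raise KnapsackParseError(f"line {lineno}: {exc}") from None
    if n is None or m is None or profits is None or capacities is None:
        raise KnapsackParseError("missing one of n/m/profits/capacities")
    if len(profits) != n or len(weights) != m or len(capacities) != m:
        raise KnapsackParseError(
            f"dimension mismatch: n={n}, m={m}, got {len(profits)} profits, "
            f"{len(weights)} weight rows, {len(capacities)} capacities")
    return KnapsackInstance(tuple(profits), tuple(map(tuple, weights)),
                            tuple(capacities))


def _parse_orlib(text: str) -> KnapsackInstance:
    """OR-Library multiple-knapsack sequence: n, m, optimum, n profits,
    m*n coefficients, m capacities (whitespace separated)."""
    toks = text.split()
    try:
        vals = [float(t) for t in toks]
    except ValueError as exc:
        raise KnapsackParseError(str(exc)) from None
    if len(vals) < 3:
        raise KnapsackParseError("truncated file: fewer than 3 tokens")
    n, m = int(vals[0]), int(vals[1])
    opt = vals[2]
    need = 3 + n + m * n + m
    if len(vals) < need:
        raise KnapsackParseError(
            f"truncated file: expected {need} numbers for n={n}, m={m}, "
            f"got {len(vals)}")
    profits = tuple(vals[3:3 + n])
    weights = tuple(tuple(vals[3 + n + j * n: 3 + n + (j + 1) * n])
                    for j in range(m))
    capacities = tuple(vals[3 + n + m * n: need])
    return KnapsackInstance(profits, weights, capacities,
                            known_optimum=opt if opt > 0 else None)


def read_knapsack(path: str, dialect: str = "native") -> KnapsackInstance:
    with open(path) as fh:
        text = fh.read()
    if dialect == "native":
        return _parse_native(text)
    if dialect == "orlib":
        return _parse_orlib(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def generate_knapsack(n: int, m: int, seed: int
                      ) -> tuple[KnapsackInstance, float]:
    """Seeded synthetic instance with integer data; capacities are set to
    about half of each knapsack's total weight so that roughly half the
    packings are infeasible.  Returns the instance with its brute-force
    optimum (also stored on the instance); requires n <= 24."""
    if n > 24:
        raise ValueError("synthetic instances are capped at n=24 so the "
                         "exhaustive oracle stays tractable")
    rng = random.Random(seed)
    profits = tuple(float(rng.randint(1, 100)) for _ in range(n))
    weights = tuple(tuple(float(rng.randint(1, 50)) for _ in range(n))
                    for _ in range(m))
    capacities = tuple(round(0.5 * sum(row)) for row in weights)
    inst = KnapsackInstance(profits, weights, capacities, name=f"synth{seed}")
    opt, _ = brute_force_knapsack(inst)
    inst.known_optimum = opt
    return inst, opt


def brute_force_knapsack(inst: KnapsackInstance
                         ) -> tuple[float, tuple[int, ...]]:
    """Exhaustive optimum over all 2^n packings (n <= 24)."""
    n = inst.n
    if n > 24:
        raise ValueError("brute force capped at n=24")
    p = np.asarray(inst.profits)
    w = np.asarray(inst.weights)          # m x n
    c = np.asarray(inst.capacities)
    best_val, best_x = 0.0, (0,) * n
    bits = np.arange(n)
    for lo in range(0, 1 << n, 1 << 16):
        masks = np.arange(lo, min(lo + (1 << 16), 1 << n), dtype=np.int64)
        sel = (masks[:, None] >> bits) & 1          # chunk x n
        feas = np.all(sel @ w.T <= c, axis=1)
        if not feas.any():
            continue
        vals = sel[feas] @ p
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_x = tuple(int(b) for b in sel[feas][k])
    return best_val, best_x


# ----------------------------------------------------------------------
# continuous De Jong-style functions (all minimized, minimum 0)
# ----------------------------------------------------------------------
DE_JONG_BOUNDS = {
    "sphere": (-5.12, 5.12),
    "rosenbrock": (-2.048, 2.048),
    "quartic": (-1.28, 1.28),
    "rastrigin": (-5.12, 5.12),
}


def sphere(x: Sequence[float]) -> float:
    return float(sum(v * v for v in x))


def rosenbrock(x: Sequence[float]) -> float:
    return float(sum(100.0 * (x[i + 1] - x[i] ** 2) ** 2 + (1.0 - x[i]) ** 2
                     for i in range(len(x) - 1)))


def quartic_noise(x: Sequence[float], rng: random.Random | None = None,
                  noise: bool = True) -> float:
    """De Jong's quartic, sum of i*x_i^4 (1-based i) plus uniform [0,1)
    noise per evaluation; the noise term can be switched off for
    deterministic tests."""
    base = sum((i + 1) * v ** 4 for i, v in enumerate(x))
    if noise:
        base += (rng or random).random()
    return float(base)


def rastrigin(x: Sequence[float]) -> float:
    return float(10.0 * len(x) +
                 sum(v * v - 10.0 * math.cos(2.0 * math.pi * v) for v in x))


def decode_continuous(phenotype: Sequence[float],
                      bounds: tuple[float, float]) -> tuple[float, ...]:
    """Affine map of node labels in [-1, 1] onto the problem domain."""
    lo, hi = bounds
    return tuple(lo + (v + 1.0) * 0.5 * (hi - lo) for v in phenotype)


# ----------------------------------------------------------------------
# HIFF and royal road
# ----------------------------------------------------------------------
def _as_bits(s) -> list[int]:
    if isinstance(s, str):
        return [int(ch) for ch in s]
    return [int(b) for b in s]


def hiff(s, variant: str = "paper") -> float:
    """Hierarchical if-and-only-if fitness for a length-2^H binary string.

    Adjacent pairs pass through the transfer function [0,0]->0, [1,1]->1,
    anything else -> NULL; each level's contribution is the count of its
    non-NULL entries times the level multiplier, and the transfer is applied
    recursively until a single top entry remains.  The ``paper`` variant
    starts scoring at the pair level with multipliers 1, 2, 4, ...; the
    ``watson`` variant additionally scores the single-bit level (every bit
    counts 1) and doubles block weight per level, yielding the classic
    values (e.g. 448 for 64 set bits).  Global optima: all ones, all zeros.
    """
    bits = _as_bits(s)
    n = len(bits)
    if n < 2 or n & (n - 1):
        raise ValueError(f"HIFF needs a power-of-two length >= 2, got {n}")
    total = 0.0
    level = [b for b in bits]
    mult = 1.0
    if variant == "watson":
        total += len(level)     # single-bit contributions
        mult = 2.0
    elif variant != "paper":
        raise ValueError(f"unknown HIFF variant {variant!r}")
    while len(level) > 1:
        nxt = []
        for a, b in zip(level[::2], level[1::2]):
            nxt.append(a if a is not None and a == b else None)
        total += mult * sum(1 for v in nxt if v is not None)
        level = nxt
        mult *= 2.0
    return total


def _hiff_optimum(n: int, variant: str) -> float:
    return hiff([1] * n, variant)


ROYAL_ROAD_BLOCK = 8


def royal_road(s) -> float:
    """Royal road over 64 bits: 8 points for each of the eight disjoint
    contiguous 8-bit all-ones schemata matched; maximum 64."""
    bits = _as_bits(s)
    if len(bits) != 64:
        raise ValueError(f"royal road is defined on 64 bits, got {len(bits)}")
    score = 0.0
    for i in range(0, 64, ROYAL_ROAD_BLOCK):
        if all(bits[i:i + ROYAL_ROAD_BLOCK]):
            score += 8.0
    return score


def alternating_count(s, generation: int, period: int) -> float:
    """Alternating counting-ones / counting-zeros: phase 0 rewards ones,
    phase 1 rewards zeros, switching every ``period`` generations."""
    if period < 1:
        raise ValueError("period must be >= 1")
    bits = _as_bits(s)
    phase = (generation // period) % 2
    ones = sum(bits)
    return float(ones if phase == 0 else len(bits) - ones)


# ----------------------------------------------------------------------
# FitnessFunction factories
# ----------------------------------------------------------------------
def counting_ones_fitness(L: int) -> FitnessFunction:
    return FitnessFunction("counting_ones", BINARY,
                           lambda s, g: float(sum(_as_bits(s))),
                           minimize=False, optimum=float(L))


def knapsack_fn(inst: KnapsackInstance) -> FitnessFunction:
    return FitnessFunction(f"knapsack:{inst.name}", BINARY,
                           lambda s, g: knapsack_fitness(_as_bits(s), inst),
                           minimize=False, optimum=inst.known_optimum)


def hiff_fitness(n: int, variant: str = "paper") -> FitnessFunction:
    return FitnessFunction(f"hiff{n}", BINARY,
                           lambda s, g: hiff(s, variant),
                           minimize=False, optimum=_hiff_optimum(n, variant))


def royal_road_fitness() -> FitnessFunction:
    return FitnessFunction("royal_road64", BINARY,
                           lambda s, g: royal_road(s),
                           minimize=False, optimum=64.0)


def alternating_fitness(L: int, period: int) -> FitnessFunction:
    return FitnessFunction(f"alternating{L}", BINARY,
                           lambda s, g: alternating_count(s, g, period),
                           minimize=False, optimum=float(L))


def _continuous_fn(name: str, f: Callable, L: int) -> FitnessFunction:
    bounds = DE_JONG_BOUNDS[name]
    return FitnessFunction(
        name, CONTINUOUS,
        lambda s, g: f(decode_continuous(s, bounds)),
        minimize=True, bounds=bounds, optimum=None)


def sphere_fitness(L: int) -> FitnessFunction:
    return _continuous_fn("sphere", sphere, L)


def rosenbrock_fitness(L: int) -> FitnessFunction:
    return _continuous_fn("rosenbrock", rosenbrock, L)


def rastrigin_fitness(L: int) -> FitnessFunction:
    return _continuous_fn("rastrigin", rastrigin, L)


def quartic_fitness(L: int, noise: bool = True,
                    seed: int | None = None) -> FitnessFunction:
    rng = random.Random(seed)
    bounds = DE_JONG_BOUNDS["quartic"]
    return FitnessFunction(
        "quartic", CONTINUOUS,
        lambda s, g: quartic_noise(decode_continuous(s, bounds), rng, noise),
        minimize=True, bounds=bounds, optimum=None)
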