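"""Microbial genetic algorithm baseline.

A minimal steady-state GA over discrete, non-overlapping genotypes: each
step draws two distinct random individuals, the loser of the pairwise
tournament is overwritten by the winner — wholly (no-crossover variant) or
per-locus with the infection probability (recombination variant) — and then
mutated.  The winner is never modified.  Traces are indexed by fitness
evaluations (two per tournament) so they align with the path engine's
two-evaluations-per-generation schedule.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .engine import RunTrace
from .network import BINARY, CONTINUOUS

__all__ = ["GAConfig", "microbial_step", "run_ga"]


@dataclass
class GAConfig:
    pop_size: int = 100
    L: int = 10
    mu: float = 0.0                # per-locus mutation probability
    infection: float = 1.0         # per-locus copy probability; 1.0 with
    crossover: bool = False        # crossover=False means whole-genome copy
    minimize: bool = False
    generations: int = 1000        # tournaments
    seed: int = 0
    scheme: str = BINARY
    mutation_sd: float = 0.1
    log_every: int = 1
    stop_at_target: bool = False

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for name in ("mu", "infection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _random_genotype(L: int, scheme: str, rng: random.Random) -> list:
    if scheme == BINARY:
        return [rng.randint(0, 1) for _ in range(L)]
    return [rng.uniform(-1.0, 1.0) for _ in range(L)]


def _mutate(geno: list, mu: float, scheme: str, sd: float,
            rng: random.Random) -> None:
    if mu <= 0.0:
        return
    for i in range(len(geno)):
        if rng.random() < mu:
            if scheme == BINARY:
                geno[i] = 1 - geno[i]
            else:
                geno[i] = min(1.0, max(-1.0, rng.gauss(geno[i], sd)))


def microbial_step(pop: list[list], fitness, cfg: GAConfig,
                   rng: random.Random, generation: int = 0
                   ) -> tuple[float, float]:
    """One microbial tournament; mutates ``pop`` in place and returns the
    two rewards drawn."""
    i = rng.randrange(len(pop))
    j = rng.randrange(len(pop) - 1)
    if j >= i:
        j += 1
    fi = fitness(pop[i], generation)
    fj = fitness(pop[j], generation)
    if math.isnan(fi) or math.isnan(fj):
        raise ValueError("NaN reward")
    # strict comparison, ties resolved against the second pick: equal-fitness
    # pairs still infect, giving the population neutral drift
    i_better = (fi < fj) if cfg.minimize else (fi > fj)
    win, lose = (i, j) if i_better else (j, i)
    if cfg.crossover:
        for k in range(cfg.L):
            if rng.random() < cfg.infection:
                pop[lose][k] = pop[win][k]
    else:
        pop[lose] = list(pop[win])
    _mutate(pop[lose], cfg.mu, cfg.scheme, cfg.mutation_sd, rng)
    return fi, fj


def run_ga(cfg: GAConfig, fitness) -> RunTrace:
    """Run the microbial GA; trace mirrors :func:`pathevo.engine.run_pea`.

    Diversity is the count of distinct genotypes in the population at
    logging time.
    """
    scheme = getattr(fitness, "scheme", cfg.scheme)
    minimize = getattr(fitness, "minimize", cfg.minimize)
    optimum = getattr(fitness, "optimum", None)
    rng = random.Random(cfg.seed)
    pop = [_random_genotype(cfg.L, scheme, rng) for _ in range(cfg.pop_size)]
    trace = RunTrace(evaluations_per_generation=2)
    best = math.inf if minimize else -math.inf
    better = min if minimize else max
    for gen in range(cfg.generations):
        fi, fj = microbial_step(pop, fitness, cfg, rng, gen)
        best = better(best, fi, fj)
        if optimum is not None and trace.first_hit_generation is None \
                and (fi == optimum or fj == optimum):
            trace.first_hit_generation = gen
        if gen % cfg.log_every == 0 or gen == cfg.generations - 1 \
                or (cfg.stop_at_target and best == optimum):
            distinct = len({tuple(g) for g in pop})
            trace.log(gen, fi, fj, best, 0, 0, distinct)
        if cfg.stop_at_target and optimum is not None and best == optimum:
            break
    trace.population = pop
    return trace
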