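"""Reproducible experiment harness: named recipes, seeded batteries, summaries.

Each recipe bundles a figure-level experiment's parameter set (taken verbatim
from the corresponding caption where one exists) with the fitness function it
was run against, so a battery of independent seeded runs can be launched with
one call and its traces and summary statistics regenerated exactly.  The
``scale`` knob multiplies generation budgets (and the environment-oscillation
period, where applicable) for desk-scale reruns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from . import benchmarks as bm
from .engine import PEAConfig, RunTrace, run_pea
from .ga import GAConfig, run_ga

__all__ = [
    "ExperimentRecipe", "SummaryStats", "RECIPES",
    "run_battery", "memory_metric", "compare_batteries",
    "load_config", "apply_config",
]

#: caption-name aliases for PEAConfig/GAConfig fields in flat config files
CONFIG_ALIASES = {
    "lambda": "lam", "mu": "mu", "chi": "chi", "tau": "tau",
    "omega": "omega", "rho": "rho", "gamma": "gamma",
    "max_nodes": "max_nodes_per_layer",
}


def load_config(path: str) -> dict:
    """Flat YAML key-value run configuration; caption spellings accepted."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat mapping")
    return {CONFIG_ALIASES.get(k, k): v for k, v in raw.items()}


def apply_config(cfg, overrides: dict):
    """Dataclass copy with overridden fields (unknown keys rejected)."""
    names = {f.name for f in dataclasses.fields(cfg)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return dataclasses.replace(cfg, **overrides)


@dataclass
class ExperimentRecipe:
    """A named, figure-level experiment: fitness factory + parameter sets.

    ``fitness_factory(scale)`` builds the fitness function (the scale only
    matters for time-varying environments); ``pea`` and (optionally) ``ga``
    hold the caption parameter sets; ``scaled_generations`` applies the
    scale factor to the generation budget.
    """

    name: str
    fitness_factory: Callable[[float], object]
    pea: PEAConfig
    ga: GAConfig | None = None
    notes: str = ""

    def scaled(self, scale: float) -> tuple[PEAConfig, GAConfig | None]:
        gens = max(1, int(round(self.pea.generations * scale)))
        pea = dataclasses.replace(self.pea, generations=gens)
        ga = None
        if self.ga is not None:
            # one PEA generation = 2 evaluations = 1 microbial tournament
            ga = dataclasses.replace(self.ga, generations=gens)
        return pea, ga


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    max: float
    min: float

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        return cls(n=len(v), mean=float(v.mean()),
                   sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                   max=float(v.max()), min=float(v.min()))


def _memory_fitness(scale: float):
    period = max(1, int(round(25000 * scale)))
    return bm.alternating_fitness(64, period)


def _build_recipes() -> dict[str, ExperimentRecipe]:
    r: dict[str, ExperimentRecipe] = {}
    r["fig10_knapsack"] = ExperimentRecipe(
        "fig10_knapsack",
        lambda scale, _inst=[None]: bm.knapsack_fn(_inst[0])
        if _inst[0] is not None else None,
        PEAConfig(N=1, L=105, lam=0.1, mu=1 / 105, chi=0.0, tau=200,
                  omega=0.01, gamma=0.0, generations=10000,
                  max_nodes_per_layer=100, log_every=10),
        GAConfig(pop_size=100, L=105, mu=1 / 105, generations=10000,
                 log_every=10),
        notes="needs an external Weing8-style instance file (--instance); "
              "see knapsack_synth for a self-contained variant")
    inst16, _ = bm.generate_knapsack(16, 2, seed=7)
    r["knapsack_synth"] = ExperimentRecipe(
        "knapsack_synth",
        lambda scale, inst=inst16: bm.knapsack_fn(inst),
        PEAConfig(N=1, L=16, lam=0.1, mu=1 / 16, chi=0.0, tau=200,
                  omega=0.01, gamma=0.0, generations=10000,
                  max_nodes_per_layer=16, log_every=10),
        GAConfig(pop_size=100, L=16, mu=1 / 16, generations=10000,
                 log_every=10),
        notes="synthetic 16-object, 2-knapsack instance with brute-force "
              "optimum")
    for fname, factory in (("sphere", bm.sphere_fitness),
                           ("rosenbrock", bm.rosenbrock_fitness),
                           ("quartic", bm.quartic_fitness)):
        r[f"fig11_{fname}"] = ExperimentRecipe(
            f"fig11_{fname}",
            lambda scale, f=factory: f(20),
            PEAConfig(N=100, L=20, lam=0.1, mu=1 / 20, chi=0.01, tau=100,
                      omega=0.01, gamma=0.0, scheme="continuous",
                      generations=10000, max_nodes_per_layer=100,
                      log_every=10, minimize=True),
            GAConfig(pop_size=100, L=20, mu=1 / 20, crossover=True,
                     infection=0.5, scheme="continuous", minimize=True,
                     generations=10000, log_every=10))
    r["fig12_rastrigin_shc"] = ExperimentRecipe(
        "fig12_rastrigin_shc",
        lambda scale: bm.rastrigin_fitness(20),
        PEAConfig(N=100, L=20, lam=0.1, mu=1 / 20, chi=0.01, tau=100,
                  omega=0.01, gamma=0.0, scheme="continuous",
                  generations=20000, max_nodes_per_layer=100, log_every=10,
                  minimize=True),
        notes="hill-climber-like parameter set: low tau, no exploration "
              "noise, shared edges unpunished")
    r["fig12_rastrigin_ga"] = ExperimentRecipe(
        "fig12_rastrigin_ga",
        lambda scale: bm.rastrigin_fitness(20),
        PEAConfig(N=100, L=20, lam=0.1, mu=1 / 1000, chi=0.01,
                  tau=1000, omega=0.01, gamma=0.01, scheme="continuous",
                  generations=20000, max_nodes_per_layer=100, log_every=10,
                  minimize=True, punish_shared=True),
        GAConfig(pop_size=100, L=20, mu=1 / 1000, crossover=True,
                 infection=0.5, scheme="continuous", minimize=True,
                 generations=20000, log_every=10),
        notes="diversity-preserving parameter set: long tau, exploration "
              "noise, shared edges punished like the loser")
    r["fig13_memory"] = ExperimentRecipe(
        "fig13_memory",
        _memory_fitness,
        PEAConfig(N=100, L=64, lam=0.1, mu=1 / 100, chi=0.0,
                  tau=1000, omega=0.01, gamma=0.0, generations=200000,
                  max_nodes_per_layer=4, log_every=1),
        GAConfig(pop_size=100, L=64, mu=1 / 100, generations=200000,
                 log_every=1),
        notes="alternating counting-ones/zeros; oscillation period 25000 "
              "generations at scale 1, scaled with the budget")
    r["fig14_hiff"] = ExperimentRecipe(
        "fig14_hiff",
        lambda scale: bm.hiff_fitness(64),
        PEAConfig(N=10, L=64, lam=0.1, mu=1 / 100, chi=0.0,
                  tau=10000, omega=0.01, gamma=0.0, generations=200000,
                  max_nodes_per_layer=20, log_every=100, stop_at_target=True),
        GAConfig(pop_size=100, L=64, mu=1 / 100, generations=200000,
                 log_every=100, stop_at_target=True))
    r["fig15_royalroad"] = ExperimentRecipe(
        "fig15_royalroad",
        lambda scale: bm.royal_road_fitness(),
        PEAConfig(N=10, L=64, lam=0.1, mu=1 / 64, chi=0.0, tau=2000,
                  omega=0.01, gamma=0.0, generations=50000,
                  max_nodes_per_layer=20, log_every=50),
        GAConfig(pop_size=100, L=64, mu=1 / 64, generations=50000,
                 log_every=50),
        notes="node/edge counts expand while schemata are being searched "
              "and contract once found")
    return r


RECIPES = _build_recipes()


@dataclass
class _ScaledMemoryExperiment:
    """Desk-scale alternating-environment experiment: 32-bit alternating
    counting-ones/zeros with a 5,000-generation oscillation period over
    40,000 generations (eight environmental switches), path engine versus
    microbial GA.  The layer cap of 4 and the N >> cap initialization mirror
    the full-scale memory experiment's geometry."""

    L: int = 32
    period: int = 5000
    generations: int = 40000

    def run(self, seed: int) -> dict:
        fitness = bm.alternating_fitness(self.L, self.period)
        switches = list(range(0, self.generations, self.period))
        pea_cfg = PEAConfig(N=20, L=self.L, lam=0.1, mu=0.01, chi=0.0,
                            tau=1000, omega=0.01, gamma=0.0,
                            max_nodes_per_layer=4,
                            generations=self.generations, seed=seed,
                            log_every=1)
        ga_cfg = GAConfig(pop_size=100, L=self.L, mu=0.01,
                          generations=self.generations, seed=seed,
                          log_every=1)
        tr = run_pea(pea_cfg, fitness)
        tg = run_ga(ga_cfg, fitness)
        return {
            "pea": memory_metric(tr, switches, optimum=float(self.L)),
            "ga": memory_metric(tg, switches, optimum=float(self.L)),
        }


MEMORY_SCALED = _ScaledMemoryExperiment()


def run_battery(recipe: ExperimentRecipe, replicates: int = 5,
                seed_base: int = 0, scale: float = 1.0,
                outdir: str | None = None, with_ga: bool = True,
                fitness=None) -> dict:
    """Independent seeded runs of a recipe; returns traces and summaries.

    Per-run traces are written to ``outdir`` as CSV when given.  Failures
    are recorded per run and the battery continues.
    """
    fitness = fitness if fitness is not None else \
        recipe.fitness_factory(scale)
    if fitness is None:
        raise ValueError(f"recipe {recipe.name} needs an external instance")
    pea_cfg, ga_cfg = recipe.scaled(scale)
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"recipe": recipe.name, "scale": scale,
                     "pea_traces": [], "ga_traces": [], "errors": []}
    for k in range(replicates):
        seed = seed_base + k
        try:
            tr = run_pea(dataclasses.replace(pea_cfg, seed=seed), fitness)
            results["pea_traces"].append(tr)
            if out:
                tr.to_csv(out / f"{recipe.name}_pea_seed{seed}.csv")
        except Exception as exc:   # battery continues past per-run failures
            results["errors"].append(("pea", seed, repr(exc)))
        if with_ga and ga_cfg is not None:
            try:
                tg = run_ga(dataclasses.replace(ga_cfg, seed=seed), fitness)
                results["ga_traces"].append(tg)
                if out:
                    tg.to_csv(out / f"{recipe.name}_ga_seed{seed}.csv")
            except Exception as exc:
                results["errors"].append(("ga", seed, repr(exc)))
    for key, traces in (("pea", results["pea_traces"]),
                        ("ga", results["ga_traces"])):
        if traces:
            results[f"{key}_summary"] = SummaryStats.from_values(
                [t.final_best for t in traces])
    if results["pea_traces"] and results["ga_traces"]:
        results["comparison"] = compare_batteries(
            [t.final_best for t in results["pea_traces"]],
            [t.final_best for t in results["ga_traces"]])
    return results


def compare_batteries(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of final best fitness."""
    from scipy.stats import mannwhitneyu

    stat, p = mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"U": float(stat), "p_value": float(p)}


def memory_metric(trace: RunTrace, switch_generations, optimum: float
                  ) -> dict:
    """Recovery times after each environmental switch, and their trend.

    For each switch generation, the recovery time is the number of
    generations until the per-generation best reward re-attains the
    environment's optimum; if it never does before the next switch the
    time is censored there.  The memory score is the least-squares slope of
    recovery time against switch index (negative slope: the algorithm
    re-finds old optima faster on re-presentation).
    """
    gens = np.asarray(trace.generation)
    cur = np.maximum(np.asarray(trace.reward_a), np.asarray(trace.reward_b))
    switches = sorted(switch_generations)
    times, censored = [], []
    for k, s in enumerate(switches):
        end = switches[k + 1] if k + 1 < len(switches) else gens[-1] + 1
        window = (gens >= s) & (gens < end)
        hit = np.nonzero(window & (cur >= optimum))[0]
        if len(hit):
            times.append(float(gens[hit[0]] - s))
            censored.append(False)
        else:
            times.append(float(end - s))
            censored.append(True)
    result = {"recovery_times": times, "censored": censored}
    if len(times) >= 2:
        from scipy.stats import linregress

        fit = linregress(range(len(times)), times)
        result["slope"] = float(fit.slope)
        result["slope_p"] = float(fit.pvalue)
    return result
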