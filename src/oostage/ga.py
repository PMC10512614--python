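"""Genetic-algorithm refinement of the classifier's filter-count chromosome.

The GA minimizes a two-part objective that trades classification quality
against the filter budget of the network,

    OF = 1 − Acc̄ + ΣF_k / F_max,          F_max = 128 · 6,

where Acc̄ is the mean validation accuracy returned by an evaluator and ΣF_k
sums the chromosome's six filter counts.  With accuracy in [0, 1] and legal
chromosomes, OF lies in [12/768, 2].

Evolution is generational with elitism: the best individual (with its
recorded score — noisy evaluators are not re-evaluated) is copied unchanged
into the next generation, so the per-generation best OF is non-increasing.
Parents are chosen by size-2 tournaments; offspring undergo uniform per-gene
crossover and a per-gene ±2k mutation (k ≤ mutation_span) clipped to the
even grid in [2, 128].  Evaluations are cached by chromosome so repeated individuals
cost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import Chromosome, FILTER_BOUNDS, N_GENES

__all__ = ["GAConfig", "EvaluatedIndividual", "objective", "mutate", "crossover", "evolve", "F_MAX"]

F_MAX = FILTER_BOUNDS[1] * N_GENES  # 128 * 6 = 768


@dataclass(frozen=True)
class GAConfig:
    generations: int = 10
    population_size: int = 10
    elite_count: int = 1
    mutation_rate: float = 0.4
    mutation_span: int = 8     # per-gene step is +-2k, k in [1, mutation_span]
    crossover_rate: float = 0.7
    seed: int = 0

    def validate(self) -> "GAConfig":
        if self.generations < 1 or self.population_size < 1:
            raise ValueError("generations and population size must be >= 1")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite count must satisfy 0 <= elite < population size")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        return self


@dataclass(frozen=True)
class EvaluatedIndividual:
    chromosome: Chromosome
    accuracy: float
    of: float


def objective(acc: float, chromosome: Chromosome | tuple[int, ...], f_max: int = F_MAX) -> float:
    """OF = 1 − Acc̄ + ΣF_k / F_max."""
    if not 0 <= acc <= 1:
        raise ValueError(f"accuracy {acc} outside [0, 1]")
    if not isinstance(chromosome, Chromosome):
        chromosome = Chromosome(tuple(chromosome))
    return 1.0 - acc + chromosome.total / f_max


def _clip_even(v: int) -> int:
    lo, hi = FILTER_BOUNDS
    v = max(lo, min(hi, v))
    return v if v % 2 == 0 else v - 1


def mutate(chromosome: Chromosome, cfg: GAConfig, rng: np.random.Generator | int) -> Chromosome:
    """Per-gene ±2k perturbation (k ≤ mutation_span) with probability mutation_rate."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    genes = list(chromosome.filters)
    for i in range(len(genes)):
        if rng.uniform() < cfg.mutation_rate:
            step = 2 * int(rng.integers(1, cfg.mutation_span + 1)) * (1 if rng.uniform() < 0.5 else -1)
            genes[i] = _clip_even(genes[i] + step)
    return Chromosome(tuple(genes))


def crossover(a: Chromosome, b: Chromosome, cfg: GAConfig, rng: np.random.Generator | int) -> Chromosome:
    """Uniform per-gene crossover."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    genes = tuple(ga if rng.uniform() < 0.5 else gb for ga, gb in zip(a.filters, b.filters))
    return Chromosome(genes)


def random_chromosome(rng: np.random.Generator) -> Chromosome:
    lo, hi = FILTER_BOUNDS
    return Chromosome(tuple(int(2 * rng.integers(lo // 2, hi // 2 + 1)) for _ in range(N_GENES)))


def evolve(evaluator, cfg: GAConfig | None = None) -> tuple[EvaluatedIndividual, pd.DataFrame]:
    """Run the GA; returns the best individual and a per-generation history.

    ``evaluator(chromosome) -> Acc̄`` must return a value for every legal
    chromosome.  History columns: generation, best_of, best_acc, best_sum,
    chromosome, mean_sum.
    """
    cfg = (cfg or GAConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def score(ch: Chromosome) -> EvaluatedIndividual:
        key = ch.filters
        if key not in cache:
            try:
                acc = float(evaluator(ch))
            except Exception as exc:  # surface the offending chromosome
                raise RuntimeError(f"evaluator failed on chromosome {key}: {exc}") from exc
            cache[key] = acc
        return EvaluatedIndividual(ch, cache[key], objective(cache[key], ch))

    population = [score(random_chromosome(rng)) for _ in range(cfg.population_size)]
    history = []
    best_overall: EvaluatedIndividual | None = None
    for gen in range(1, cfg.generations + 1):
        population.sort(key=lambda e: e.of)
        gen_best = population[0]
        if best_overall is None or gen_best.of < best_overall.of:
            best_overall = gen_best
        history.append(
            {
                "generation": gen,
                "best_of": gen_best.of,
                "best_acc": gen_best.accuracy,
                "best_sum": gen_best.chromosome.total,
                "chromosome": list(gen_best.chromosome.filters),
                "mean_sum": float(np.mean([e.chromosome.total for e in population])),
            }
        )
        if gen == cfg.generations:
            break
        # elites survive with their recorded scores
        next_pop = population[: cfg.elite_count]
        while len(next_pop) < cfg.population_size:
            def pick() -> Chromosome:
                i, j = rng.integers(0, cfg.population_size, size=2)
                return min(population[i], population[j], key=lambda e: e.of).chromosome

            child = pick()
            if rng.uniform() < cfg.crossover_rate:
                child = crossover(child, pick(), cfg, rng)
            child = mutate(child, cfg, rng)
            next_pop.append(score(child))
        population = next_pop
    return best_overall, pd.DataFrame(history)
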