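"""Island-parallel evolution with gene-flow events and the top-level run loop.

The population is randomly split into NC equally sized subpopulations
("islands") that evolve independently for NG generations; merging them back
is a gene-flow event (GFE), after which the population is re-split at
random. After NGFE such events the run terminates. Islands draw from
dedicated RNG streams (seed + island index), so sequential execution is
bit-identical to any concurrent schedule that honours the streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .diagnostics import hamming_distance
from .encoding import GenomeSpec, Individual, InterventionSet, random_individual
from .errors import ConfigurationError
from .fitness import FitnessEvaluator, FitnessResult
from .ga_core import GAConfig, generation_step

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "split_population", "gene_flow", "run"]


@dataclass
class RunResult:
    """Outcome of a GA run: final population, champion, and the trace."""

    final_population: list[Individual]
    best_individual: Individual
    best_intervention_set: InterventionSet
    trace: pd.DataFrame
    config: GAConfig
    seed: int
    n_evaluations: int = 0
    n_memo_hits: int = 0

    @property
    def best_fitness(self) -> FitnessResult:
        return self.best_individual.fitness


def split_population(
    population: list[Individual], NC: int, rng: np.random.Generator
) -> list[list[Individual]]:
    """Randomly partition the population into NC equal subpopulations."""
    NP = len(population)
    if NP % NC != 0:
        raise ConfigurationError(
            f"NP = {NP} not divisible by NC = {NC}; try NP = {NC * (NP // NC or 1)}"
        )
    perm = rng.permutation(NP)
    size = NP // NC
    return [[population[k] for k in perm[i * size:(i + 1) * size]]
            for i in range(NC)]


def gene_flow(subpopulations: list[list[Individual]]) -> list[Individual]:
    """Merge island subpopulations; no individuals are created or lost."""
    merged: list[Individual] = []
    for sub in subpopulations:
        merged.extend(sub)
    return merged


def _best(population: list[Individual]) -> Individual:
    return max(population, key=lambda ind: (ind.fitness.F_hat, -ind.fitness.I))


def run(
    evaluator: FitnessEvaluator,
    config: GAConfig,
    spec: Optional[GenomeSpec] = None,
    early_stop_hd: Optional[float] = None,
    early_stop_window: int = 10,
) -> RunResult:
    """Evolve a population of intervention sets against the evaluator.

    ``early_stop_hd`` optionally terminates a run early when the pooled
    diversity stays below the threshold for ``early_stop_window``
    consecutive generations; it is off by default, the fixed NGFE*NG budget
    being the standard termination criterion.
    """
    spec = spec or evaluator.spec
    master = np.random.default_rng(config.seed)
    island_rngs = [np.random.default_rng(config.seed + i + 1)
                   for i in range(config.NC)]

    population = [random_individual(spec, master) for _ in range(config.NP)]
    for ind in population:
        evaluator.evaluate(ind)

    records: list[dict] = []
    global_best = _best(population).copy()
    gen = 0
    evals_before = evaluator.n_evaluations
    low_hd_streak = 0
    stopped = False

    for gfe in range(config.NGFE):
        islands = split_population(population, config.NC, master)
        for g in range(config.NG):
            gen += 1
            gen_hds = []
            for i, island in enumerate(islands):
                evals0 = evaluator.n_evaluations
                islands[i] = generation_step(
                    island, config, spec, evaluator.evaluate, island_rngs[i])
                stats = hamming_distance(islands[i])
                gen_hds.append(stats.HD)
                fhats = [ind.fitness.F_hat for ind in islands[i]]
                records.append({
                    "gfe": gfe,
                    "generation": gen,
                    "island": i,
                    "max_fitness": max(fhats),
                    "mean_fitness": float(np.mean(fhats)),
                    "hd": stats.HD,
                    "evals": evaluator.n_evaluations - evals0,
                })
                cand = _best(islands[i])
                if cand.fitness.F_hat > global_best.fitness.F_hat:
                    global_best = cand.copy()
            if early_stop_hd is not None:
                low_hd_streak = low_hd_streak + 1 if float(
                    np.mean(gen_hds)) < early_stop_hd else 0
                if low_hd_streak >= early_stop_window:
                    logger.info("diversity stagnated; stopping at generation %d", gen)
                    stopped = True
                    break
        population = gene_flow(islands)
        # keep the all-time champion in the pool so the best fitness is
        # monotone across gene-flow reshuffles
        if global_best.key() not in {ind.key() for ind in population}:
            worst = min(range(len(population)),
                        key=lambda k: population[k].fitness.F_hat)
            population[worst] = global_best.copy()
        if stopped:
            break

    trace = pd.DataFrame.from_records(records)
    best = global_best
    return RunResult(
        final_population=population,
        best_individual=best,
        best_intervention_set=evaluator.decode_individual(best),
        trace=trace,
        config=config,
        seed=config.seed,
        n_evaluations=evaluator.n_evaluations - evals_before,
        n_memo_hits=evaluator.n_memo_hits,
    )
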