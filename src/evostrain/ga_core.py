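"""Core genetic-algorithm operators.

One generation is: truncation selection of the NS fittest individuals,
roulette-wheel assembly of mating pairs, single-point crossover at slot
boundaries, bit-flip mutation (the best individual is exempt: elitism), and
evaluation of the new individuals. Fitness here always means the transformed
fitness F_hat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .encoding import GenomeSpec, Individual
from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "SelectionState",
    "select",
    "roulette_weights",
    "sample_pairs",
    "crossover",
    "mutate",
    "adaptive_rate",
    "generation_step",
]


@dataclass
class GAConfig:
    """Run parameters of the genetic algorithm.

    Defaults follow the settings found advantageous for strain-design
    problems: population 20, selection rate 0.25, mutation rate 0.05, and 60
    generations between gene-flow events.
    """

    NP: int = 20                 #: population size
    X: float = 0.25              #: selection rate in (0, 1)
    R: float = 0.05              #: per-bit mutation rate in [0, 1]
    ND: int = 5                  #: deletion slots per individual
    NI: int = 0                  #: insertion slots per individual
    NC: int = 1                  #: islands (parallel subpopulations)
    NG: int = 60                 #: generations per gene-flow event
    NGFE: int = 5                #: number of gene-flow events
    y: float = 0.0               #: intervention-minimization trade-off factor
    Imax: Optional[int] = None   #: max unique perturbations (default ND+NI)
    Pmin_coeff: float = 0.1      #: zero-fitness floor: Pmin = Pmin_coeff / NS
    adaptive: bool = False       #: per-individual adaptive mutation rates
    Xmin: float = 0.01           #: adaptive mutation lower bound
    Xmax: float = 0.1            #: adaptive mutation upper bound
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.X < 1:
            raise ConfigurationError("selection rate X must be in (0, 1)")
        if not 0 <= self.R <= 1:
            raise ConfigurationError("mutation rate R must be in [0, 1]")
        if self.NP < 4:
            raise ConfigurationError("population size NP must be >= 4")
        if self.NC < 1:
            raise ConfigurationError("NC must be >= 1")
        if self.NP % self.NC != 0:
            good = self.NC * max(1, round(self.NP / self.NC))
            raise ConfigurationError(
                f"NP = {self.NP} is not divisible by NC = {self.NC}; "
                f"try NP = {good}"
            )
        if self.NP // self.NC < 4:
            raise ConfigurationError("island size NP/NC must be >= 4")
        island_np = self.NP // self.NC
        ns = int(math.floor(island_np * self.X + 0.5))
        if (island_np - ns) % 2 == 1:
            ns -= 1
        if ns < 2:
            raise ConfigurationError(
                f"island size {island_np} with X = {self.X} leaves fewer than "
                "two survivors after the parity adjustment; raise X, NP, or "
                "lower NC"
            )
        if self.adaptive and self.Xmin > self.Xmax:
            raise ConfigurationError("adaptive mode requires Xmin <= Xmax")
        if self.y < 0:
            raise ConfigurationError("trade-off factor y must be >= 0")
        if self.Imax is None:
            self.Imax = self.ND + self.NI


@dataclass
class SelectionState:
    NS: int
    FR: float                       #: fitness of the best discarded individual
    n_pairs: int
    weights: Optional[np.ndarray] = None


def _fhat(ind: Individual) -> float:
    if ind.fitness is None:
        raise ConfigurationError("population must be evaluated before selection")
    return ind.fitness.F_hat


def _sort_key(ind: Individual):
    # fitness desc, then fewer interventions, then lexicographic genome:
    # makes runs reproducible under a fixed seed.
    return (-_fhat(ind), ind.fitness.I, ind.key())


def select(population: Sequence[Individual], X: float
           ) -> tuple[list[Individual], SelectionState]:
    """Keep the NS = round(NP*X) fittest individuals (parity-adjusted).

    NS is decremented by one when NP - NS is odd so the discarded places can
    be filled by whole offspring pairs.
    """
    NP = len(population)
    NS = int(math.floor(NP * X + 0.5))
    if (NP - NS) % 2 == 1:
        NS -= 1
    if NS < 2:
        raise ConfigurationError(
            f"NP = {NP}, X = {X} leaves NS = {NS} < 2 survivors"
        )
    ranked = sorted(population, key=_sort_key)
    survivors = ranked[:NS]
    FR = _fhat(ranked[NS]) if NS < NP else 0.0
    return survivors, SelectionState(NS=NS, FR=FR, n_pairs=(NP - NS) // 2)


def roulette_weights(fitnesses: Sequence[float], FR: float, Pmin: float
                     ) -> np.ndarray:
    """Mating probabilities proportional to fitness above the best discard.

    Default path: P_i = (F_i - FR) / sum(F - FR). When any survivor has zero
    fitness (or all excesses vanish) the scaled path
    F*_i = F_i + Pmin * sum(F) / (1 - Pmin * NS) is used instead, which
    guarantees P_i >= Pmin for every survivor.
    """
    F = np.asarray(fitnesses, dtype=float)
    if np.any(F < 0):
        raise DomainError("negative fitness values are not allowed")
    NS = len(F)
    if Pmin * NS >= 1.0:
        raise DomainError(f"Pmin = {Pmin} with NS = {NS} is not a probability")
    excess = F - FR
    if np.any(F == 0.0) or np.all(excess <= 1e-15):
        total = F.sum()
        if total <= 0.0:
            return np.full(NS, 1.0 / NS)
        scaled = F + Pmin * total / (1.0 - Pmin * NS)
        return scaled / scaled.sum()
    excess = np.clip(excess, 0.0, None)
    return excess / excess.sum()


def sample_pairs(
    survivors: Sequence[Individual],
    weights: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Draw mating pairs by two weighted draws without replacement each.

    Duplicate unordered pairs are rejected and redrawn; once every distinct
    pair has been used (or the rejection budget is spent) repetition is
    allowed and logged.
    """
    NS = len(survivors)
    if NS < 2:
        raise DomainError("need at least two survivors to form pairs")
    n_distinct = NS * (NS - 1) // 2
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    budget = 50 * max(n_pairs, 1) + 100
    allow_repeats = False
    while len(pairs) < n_pairs:
        i = int(rng.choice(NS, p=weights))
        w = weights.copy()
        w[i] = 0.0
        total = w.sum()
        if total <= 0:
            w = np.full(NS, 1.0 / (NS - 1))
            w[i] = 0.0
        else:
            w = w / total
        j = int(rng.choice(NS, p=w))
        key = (min(i, j), max(i, j))
        if key in seen and not allow_repeats:
            budget -= 1
            if len(seen) >= n_distinct or budget <= 0:
                allow_repeats = True
                logger.info("distinct mating pairs exhausted; allowing repeats")
            continue
        seen.add(key)
        pairs.append((i, j))
    return pairs


def crossover(
    pair: tuple[Individual, Individual],
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Single-point crossover at a uniformly drawn slot boundary.

    Offspring 1 takes the slots left of the cut from parent 1 and right of
    the cut from parent 2; offspring 2 is the complement. Slots are never
    split mid-binary-number.
    """
    p1, p2 = pair
    cuts = spec.slot_boundaries()
    if not cuts:  # single-slot genome: crossover degenerates to a swap
        logger.debug("single-slot genome: crossover is an identity swap")
        return p1.copy(keep_fitness=False), p2.copy(keep_fitness=False)
    cut = int(rng.choice(cuts))
    c1 = np.concatenate([p1.bits[:cut], p2.bits[cut:]])
    c2 = np.concatenate([p2.bits[:cut], p1.bits[cut:]])
    return Individual(c1), Individual(c2)


def mutate(
    individual: Individual,
    rate: float,
    rng: np.random.Generator,
    is_elite: bool = False,
) -> Individual:
    """Flip each bit independently with the given probability.

    The elite individual is returned unchanged (its fitness cache survives).
    A mutation event invalidates the fitness cache.
    """
    if not 0 <= rate <= 1:
        raise DomainError("mutation rate must be in [0, 1]")
    if is_elite:
        return individual
    flips = rng.random(len(individual.bits)) < rate
    if not flips.any():
        return individual
    return Individual(np.where(flips, 1 - individual.bits,
                               individual.bits).astype(np.uint8))


def adaptive_rate(Fi: float, Fmax: float, Fmean: float,
                  Xmin: float, Xmax: float) -> float:
    """Fitness-dependent mutation rate, clamped into [Xmin, Xmax].

    Xi = (Fmax - Fi)/(Fmax - Fmean) * (Xmax - Xmin) + Xmin: the best
    individual mutates at Xmin, individuals at or below the population mean
    at Xmax. A degenerate population (Fmax = Fmean) gets Xmax.
    """
    if Xmin > Xmax:
        raise DomainError("Xmin must be <= Xmax")
    denom = Fmax - Fmean
    if denom <= 0:
        return Xmax
    xi = (Fmax - Fi) / denom * (Xmax - Xmin) + Xmin
    return float(min(max(xi, Xmin), Xmax))


def generation_step(
    population: list[Individual],
    config: GAConfig,
    spec: GenomeSpec,
    evaluate_fn: Callable[[Individual], object],
    rng: np.random.Generator,
) -> list[Individual]:
    """Advance one generation; population size is restored exactly.

    Selection -> pair sampling -> crossover (filling the NP - NS discarded
    places, one surplus offspring dropped at random if the pairing
    overfills) -> mutation (elite exempt; per-individual adaptive rate when
    enabled) -> evaluation of new individuals.
    """
    NP = len(population)
    survivors, state = select(population, config.X)
    fits = [_fhat(s) for s in survivors]
    Pmin = config.Pmin_coeff / state.NS
    weights = roulette_weights(fits, state.FR, Pmin)
    state.weights = weights

    n_fill = NP - state.NS
    n_pairs = (n_fill + 1) // 2
    pairs = sample_pairs(survivors, weights, n_pairs, rng)
    offspring: list[Individual] = []
    for i, j in pairs:
        offspring.extend(crossover((survivors[i], survivors[j]), spec, rng))
    if len(offspring) > n_fill:
        drop = int(rng.integers(len(offspring)))
        offspring.pop(drop)

    new_pop = [s.copy() for s in survivors] + offspring

    all_f = [_fhat(ind) for ind in population]
    Fmax, Fmean = max(all_f), float(np.mean(all_f))
    mutated: list[Individual] = []
    for k, ind in enumerate(new_pop):
        is_elite = k == 0  # survivors are rank-sorted; index 0 is the best
        if config.adaptive and not is_elite:
            fi = _fhat(ind) if ind.fitness is not None else Fmean
            rate = adaptive_rate(fi, Fmax, Fmean, config.Xmin, config.Xmax)
        else:
            rate = config.R
        mutated.append(mutate(ind, rate, rng, is_elite=is_elite))

    for ind in mutated:
        if ind.fitness is None:
            evaluate_fn(ind)
    assert len(mutated) == NP
    return mutated
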