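"""Population-diversity and convergence diagnostics.

Diversity is the normalized average Hamming distance over all individual
pairs: the number of differing bits, averaged over the NP*(NP-1)/2 pairs and
divided by the genome length. The default implementation uses the O(NP*L)
column-count identity sum_b c_b*(NP - c_b) (c_b = ones at bit b), which
equals the literal pairwise sum; the quadratic pairwise form is kept as the
reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import Individual
from .errors import DomainError

__all__ = ["DiversityStats", "hamming_distance", "pairwise_hamming_distance",
           "convergence_report"]


@dataclass(frozen=True)
class DiversityStats:
    HD: float        #: normalized average Hamming distance in [0, 1]
    NPa: int         #: number of pairs, NP*(NP-1)/2
    raw_sum: int     #: total differing bits over all pairs


def _bit_matrix(population: Sequence[Individual]) -> np.ndarray:
    if len(population) < 2:
        raise DomainError("diversity needs at least two individuals")
    B = np.stack([ind.bits for ind in population]).astype(np.int64)
    return B


def hamming_distance(population: Sequence[Individual]) -> DiversityStats:
    """Normalized average Hamming distance (fast column-count evaluation)."""
    B = _bit_matrix(population)
    NP, L = B.shape
    ones = B.sum(axis=0)
    raw = int(np.sum(ones * (NP - ones)))
    NPa = NP * (NP - 1) // 2
    return DiversityStats(HD=raw / (NPa * L), NPa=NPa, raw_sum=raw)


def pairwise_hamming_distance(population: Sequence[Individual]) -> DiversityStats:
    """Literal pairwise-sum evaluation (quadratic; reference implementation)."""
    B = _bit_matrix(population)
    NP, L = B.shape
    raw = 0
    for i in range(NP):
        for j in range(i + 1, NP):
            raw += int(np.sum(B[i] != B[j]))
    NPa = NP * (NP - 1) // 2
    return DiversityStats(HD=raw / (NPa * L), NPa=NPa, raw_sum=raw)


def convergence_report(trace: pd.DataFrame) -> dict:
    """Summarize a run trace: per-island and pooled fitness/diversity series.

    Returns per-generation pooled series (max over islands of max fitness,
    mean HD), the generation at which the maximal fitness last improved, and
    the cumulative evaluations needed to reach it.
    """
    if len(trace) == 0:
        raise DomainError("empty trace")
    t = trace.copy()
    pooled = t.groupby("generation").agg(
        max_fitness=("max_fitness", "max"),
        mean_fitness=("mean_fitness", "mean"),
        hd=("hd", "mean"),
        evals=("evals", "sum"),
    ).reset_index()
    best = pooled["max_fitness"].cummax()
    improved = pooled["max_fitness"] >= best - 1e-15
    new_best = pooled["max_fitness"] > best.shift(1, fill_value=-np.inf)
    last_improvement = int(pooled["generation"][new_best].max()) if new_best.any() else 0
    cum_evals = pooled["evals"].cumsum()
    gens_to_best = pooled["generation"] <= last_improvement
    evaluations_to_best = int(cum_evals[gens_to_best].max()) if gens_to_best.any() else 0
    per_island = t.pivot_table(index="generation", columns="island",
                               values=["max_fitness", "hd"])
    return {
        "pooled": pooled,
        "per_island": per_island,
        "last_improvement_generation": last_improvement,
        "evaluations_to_best": evaluations_to_best,
        "final_max_fitness": float(pooled["max_fitness"].iloc[-1]),
        "final_hd": float(pooled["hd"].iloc[-1]),
        "monotone_best": bool(improved.all()),
    }
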