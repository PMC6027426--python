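"""Engineering-objective fitness of intervention sets.

The single-objective default is the biomass-product coupled yield
BPCY = vP * mu / vS (mol mol^-1 h^-1), read from a MiMBl (default) or FBA
phenotype prediction of the mutant. Multi-objective mode adds the OptKnock
criterion (product rate at maximal growth) and a simplified growth-coupling
strength (GCS: ratio of the yield-space area below the guaranteed-minimum
yield to the total yield-space area), each normalized by its wild-type
theoretical maximum and combined linearly.

Fitness is transformed to favour small intervention sets,
``F_hat = F + F * y * (Imax - I)`` with trade-off factor y >= 0, and
memoized on the canonical intervention set, since duplicate phenotype LPs
dominate the runtime of a GA run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoding import GenomeSpec, Individual, InterventionSet, decode
from .errors import ConfigurationError, DomainError
from .model import MetabolicModel
from .model_io import TargetSpace
from .phenotype import (
    PhenotypePrediction,
    RateSpec,
    ReferenceState,
    YieldSpace,
    fba,
    mimbl_predict,
    predict_fba,
    yield_space,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessResult",
    "FitnessEvaluator",
    "bpcy",
    "production_at_max_growth",
    "gcs",
    "combine_multi",
    "transform_intervention_size",
]

OBJECTIVES = ("bpcy", "prod_at_max_growth", "gcs")


@dataclass
class FitnessResult:
    """Objective fitness F, transformed fitness F_hat, and their parts."""

    F: float
    F_hat: float
    components: dict[str, float]
    I: int
    normalizers: dict[str, float] = field(default_factory=dict)
    prediction: Optional[PhenotypePrediction] = None


def bpcy(pred: PhenotypePrediction) -> float:
    """Biomass-product coupled yield vP*mu/vS; 0 for infeasible or vS = 0."""
    if not pred.feasible or pred.vS <= 0.0:
        return 0.0
    return pred.vP * pred.mu / pred.vS


def production_at_max_growth(
    model_mut: MetabolicModel,
    rates: RateSpec,
    tie_break: str = "max",
) -> float:
    """Product rate with growth fixed at its FBA maximum (OptKnock criterion).

    ``tie_break='max'`` is the classic optimistic inner problem; ``'min'``
    gives the pessimistic guaranteed rate at maximal growth.
    """
    pred = predict_fba(model_mut, rates, tie_break=tie_break)
    return pred.vP if pred.feasible else 0.0


def gcs(ys: YieldSpace) -> float:
    """Simplified growth-coupling strength: guaranteed / total yield-space area."""
    if ys.area_total <= 0.0:
        return 0.0
    return float(min(max(ys.area_below_lower / ys.area_total, 0.0), 1.0))


def combine_multi(
    components: dict[str, float],
    normalizers: dict[str, float],
    weights: Optional[dict[str, float]] = None,
) -> float:
    """Linear combination of normalized objectives (equal weights by default)."""
    total = 0.0
    for name, value in components.items():
        norm = normalizers.get(name)
        if norm is None:
            raise ConfigurationError(f"missing normalizer for component {name!r}")
        if norm <= 0:
            raise ConfigurationError(f"normalizer for {name!r} must be positive")
        w = 1.0 if weights is None else weights.get(name, 1.0)
        total += w * (value / norm)
    return total


def transform_intervention_size(F: float, I: int, Imax: int, y: float) -> float:
    """Scale fitness by intervention count: F_hat = F + F*y*(Imax - I)."""
    if y < 0:
        raise DomainError("trade-off factor y must be >= 0")
    if not 0 <= I <= Imax:
        raise DomainError(f"I = {I} outside [0, Imax = {Imax}]")
    return F + F * y * (Imax - I)


class FitnessEvaluator:
    """Decode -> mutant model -> phenotype -> objective fitness, memoized.

    Parameters
    ----------
    model:
        The (preprocessed, possibly databank-merged) wild-type model.
    space, spec:
        Target space and genome layout used for decoding.
    rates:
        Reaction ids for growth, product, and substrate rates.
    objectives:
        Subset of {"bpcy", "prod_at_max_growth", "gcs"}. A single objective
        is used raw (normalizer 1); multiple objectives are normalized by
        wild-type theoretical maxima and summed.
    predictor:
        "mimbl" (default; requires/derives a reference state) or "fba"
        (maximal growth with the configured product tie-break).
    y, Imax:
        Intervention-minimization transform parameters; Imax defaults to
        ND + NI.
    """

    def __init__(
        self,
        model: MetabolicModel,
        space: TargetSpace,
        spec: GenomeSpec,
        rates: RateSpec,
        objectives: Sequence[str] = ("bpcy",),
        weights: Optional[dict[str, float]] = None,
        predictor: str = "mimbl",
        reference: Optional[ReferenceState] = None,
        y: float = 0.0,
        Imax: Optional[int] = None,
        tie_break: str = "max",
        n_grid_points: int = 20,
    ) -> None:
        unknown = set(objectives) - set(OBJECTIVES)
        if unknown:
            raise ConfigurationError(f"unknown objectives: {sorted(unknown)}")
        if not objectives:
            raise ConfigurationError("at least one objective is required")
        if predictor not in ("mimbl", "fba"):
            raise ConfigurationError(f"unknown predictor {predictor!r}")
        self.model = model
        self.space = space
        self.spec = spec
        self.rates = rates
        self.objectives = tuple(objectives)
        self.weights = weights
        self.predictor = predictor
        self.y = float(y)
        self.Imax = int(Imax) if Imax is not None else spec.ND + spec.NI
        self.tie_break = tie_break
        self.n_grid_points = n_grid_points
        if predictor == "mimbl" and reference is None:
            reference = ReferenceState.from_model_fba(model, rates)
        self.reference = reference
        self.normalizers = self._wildtype_normalizers()
        self._memo: dict[tuple, FitnessResult] = {}
        self.n_evaluations = 0
        self.n_memo_hits = 0

    # -- normalization -----------------------------------------------------

    def _max_bpcy_over_cone(self) -> float:
        """Max BPCY over the wild-type flux cone.

        BPCY is scanned over a growth-rate grid (one product-maximizing LP
        per point) and the best bracket is refined with a bounded 1-D
        search, so every mutant's BPCY stays within the normalizer up to
        solver tolerance.
        """
        from scipy.optimize import minimize_scalar

        model = self.model
        js = model.rxn_index(self.rates.substrate)
        jb = model.rxn_index(self.rates.biomass)
        _, mu_max, ok = fba(model, objective=self.rates.biomass)
        if not ok or mu_max <= 0:
            return 1.0

        def bpcy_at(mu: float) -> float:
            sub = model.copy()
            sub.lb[jb] = mu - 1e-6 * max(1.0, mu)
            sub.ub[jb] = mu + 1e-6 * max(1.0, mu)
            v, vp, ok2 = fba(sub, objective=self.rates.product, sense="max")
            if not ok2:
                return 0.0
            vs = abs(v[js])
            return vp * mu / vs if vs > 1e-9 else 0.0

        grid = np.linspace(0.0, mu_max, self.n_grid_points)
        values = np.array([bpcy_at(mu) for mu in grid])
        k = int(np.argmax(values))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(lambda mu: -bpcy_at(float(mu)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6 * max(1.0, mu_max)})
        best = max(float(values[k]), float(-res.fun))
        return best * (1 + 1e-9) if best > 0 else 1.0

    def _wildtype_normalizers(self) -> dict[str, float]:
        if len(self.objectives) == 1:
            return {self.objectives[0]: 1.0}
        norms: dict[str, float] = {}
        for name in self.objectives:
            if name == "bpcy":
                norms[name] = self._max_bpcy_over_cone()
            elif name == "prod_at_max_growth":
                _, vp_max, ok = fba(self.model, objective=self.rates.product,
                                    sense="max")
                norms[name] = vp_max if ok and vp_max > 0 else 1.0
            elif name == "gcs":
                norms[name] = 1.0
        return norms

    # -- evaluation ----------------------------------------------------------

    def mutant_model(self, iset: InterventionSet) -> MetabolicModel:
        changes: dict[str, tuple[float, float]] = {
            rid: (0.0, 0.0) for rid in iset.reaction_deletions
        }
        for rid in iset.insertions:
            changes[rid] = self.space.insertion_bounds[rid]
        return self.model.with_bounds(changes)

    def _predict(self, mutant: MetabolicModel) -> PhenotypePrediction:
        if self.predictor == "mimbl":
            return mimbl_predict(mutant, self.reference, self.rates)
        return predict_fba(mutant, self.rates, tie_break=self.tie_break)

    def score_set(self, iset: InterventionSet) -> FitnessResult:
        """Fitness of a canonical intervention set (memoized)."""
        key = iset.sort_key()
        hit = self._memo.get(key)
        if hit is not None:
            self.n_memo_hits += 1
            return hit
        self.n_evaluations += 1
        mutant = self.mutant_model(iset)
        components: dict[str, float] = {}
        pred: Optional[PhenotypePrediction] = None
        try:
            if "bpcy" in self.objectives:
                pred = self._predict(mutant)
                components["bpcy"] = bpcy(pred)
            if "prod_at_max_growth" in self.objectives:
                components["prod_at_max_growth"] = production_at_max_growth(
                    mutant, self.rates, self.tie_break)
            if "gcs" in self.objectives:
                ys = yield_space(mutant, self.rates, n_points=self.n_grid_points)
                components["gcs"] = gcs(ys)
        except Exception:
            logger.exception("solver failure for %s; scoring 0", key)
            components = {name: 0.0 for name in self.objectives}
        if len(self.objectives) == 1:
            F = components[self.objectives[0]]
        else:
            F = combine_multi(components, self.normalizers, self.weights)
        F = max(F, 0.0)
        I = min(iset.I, self.Imax)
        result = FitnessResult(
            F=F,
            F_hat=transform_intervention_size(F, I, self.Imax, self.y),
            components=components,
            I=iset.I,
            normalizers=dict(self.normalizers),
            prediction=pred,
        )
        self._memo[key] = result
        return result

    def evaluate(self, individual: Individual) -> FitnessResult:
        """Decode and score an individual, caching the result on it."""
        if individual.fitness is not None:
            return individual.fitness
        iset = decode(individual, self.space, self.spec, self.model)
        result = self.score_set(iset)
        individual.fitness = result
        return result

    def decode_individual(self, individual: Individual) -> InterventionSet:
        return decode(individual, self.space, self.spec, self.model)
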