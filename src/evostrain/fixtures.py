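"""Synthetic toy metabolic models with known optima.

The generated network is a caricature of fermentative central carbon
metabolism: substrate uptake feeds a two-step glycolysis that produces
redox equivalents (NADH), a biomass drain, a redox-balanced product branch,
a redox-consuming byproduct branch, redox-neutral overflow branches, and two
capacity-limited respiration isozymes. Deleting both respiration reactions
forces NADH reoxidation through the product branch, growth-coupling
production: the designed optimal knockout pair. A databank of candidate
insertion reactions over native metabolites includes one edge (a
higher-yield product route) that provably raises the post-knockout optimum.

All designed optima are re-verified by LP at generation time, and
:func:`brute_force_optimal` provides the exhaustive oracle the GA is tested
against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .encoding import InterventionSet, resolve_interventions
from .errors import DomainError
from .model import MetabolicModel, gpr_genes
from .model_io import TargetSpace
from .phenotype import RateSpec, ReferenceState, fba, predict_fba

__all__ = [
    "ToyModelSpec",
    "TOY_RATES",
    "make_toy_model",
    "make_databank",
    "toy_ground_truth",
    "brute_force_optimal",
]

#: rate reactions of every toy model built here
TOY_RATES = RateSpec(biomass="BIOM", product="EX_prod", substrate="EX_glc")


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the generated toy network.

    ``n_branches`` redox-neutral overflow branches pad the deletion target
    space (the default yields 12 reaction targets); ``resp_capacity`` caps
    each respiration isozyme so the wild type secretes some product and has
    a positive BPCY.
    """

    n_branches: int = 6
    uptake: float = 10.0
    resp_capacity: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise DomainError("need at least one overflow branch")
        if not 0 < 2 * self.resp_capacity < self.uptake:
            raise DomainError(
                "respiration capacity must be limiting (2*cap < uptake) so the "
                "wild type secretes product"
            )


def make_toy_model(spec: ToyModelSpec = ToyModelSpec()
                   ) -> tuple[MetabolicModel, ReferenceState]:
    """Build the toy network and its wild-type FBA reference state."""
    inf = 1000.0
    cap = spec.resp_capacity
    # (id, stoichiometry, (lb, ub), gpr, subsystem)
    reactions: list[tuple[str, dict[str, float], tuple[float, float], str, str]] = [
        ("EX_glc", {"glc": -1}, (-spec.uptake, 0.0), "", "Exchange"),
        ("GLYC1", {"glc": -1, "nad": -1, "tp": 2, "nadh": 1}, (0, inf),
         "gA1 and gA2", "Glycolysis"),
        ("GLYC2", {"tp": -1, "pyr": 1}, (0, inf), "gB", "Glycolysis"),
        ("BIOM", {"pyr": -1, "bio": 1}, (0, inf), "", "Biomass"),
        ("EX_bio", {"bio": -1}, (0, inf), "", "Exchange"),
        ("RESP1", {"nadh": -1, "nad": 1}, (0, cap), "gR1", "Oxidative Phosphorylation"),
        ("RESP2", {"nadh": -1, "nad": 1}, (0, cap), "gR2", "Oxidative Phosphorylation"),
        ("PROD", {"pyr": -1, "nadh": -1, "prod": 1, "nad": 1}, (0, inf),
         "gP1 or gP2", "Fermentation"),
        ("T_prod", {"prod": -1, "prod_e": 1}, (0, inf), "gT", "Transport"),
        ("EX_prod", {"prod_e": -1}, (0, inf), "", "Exchange"),
        ("ETOH", {"pyr": -2, "nadh": -1, "etoh": 2, "nad": 1}, (0, inf),
         "gE", "Fermentation"),
        ("EX_etoh", {"etoh": -1}, (0, inf), "", "Exchange"),
        ("LIPID", {"pyr": -1, "lip": 1}, (0, inf), "gL", "Membrane Lipid Metabolism"),
        ("EX_lip", {"lip": -1}, (0, inf), "", "Exchange"),
    ]
    for k in range(1, spec.n_branches + 1):
        reactions.append((f"BYP{k}", {"pyr": -1, f"by{k}": 1}, (0, inf),
                          f"gOV{k}", "Overflow"))
        reactions.append((f"EX_by{k}", {f"by{k}": -1}, (0, inf), "", "Exchange"))

    mets: list[str] = []
    for _, stoich, *_ in reactions:
        for m in stoich:
            if m not in mets:
                mets.append(m)
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_, stoich, *_rest) in enumerate(reactions):
        for m, coef in stoich.items():
            S[midx[m], j] = coef

    genes: list[str] = []
    for *_ignored, gpr, _sub in reactions:
        for g in gpr_genes(gpr):
            if g not in genes:
                genes.append(g)

    model = MetabolicModel(
        metabolites=mets,
        reactions=[r[0] for r in reactions],
        S=S,
        lb=np.array([r[2][0] for r in reactions], dtype=float),
        ub=np.array([r[2][1] for r in reactions], dtype=float),
        objective_reaction="BIOM",
        gpr=[r[3] for r in reactions],
        subsystem=[r[4] for r in reactions],
        met_compartment=["e" if m.endswith("_e") else "c" for m in mets],
        gene_ids=genes,
    )
    reference = ReferenceState.from_model_fba(model, TOY_RATES)
    reference.validate(model)
    return model, reference


def make_databank(
    model: MetabolicModel,
    n_candidates: int = 3,
    insertion_yield: float = 1.5,
) -> MetabolicModel:
    """Candidate insertion reactions over native metabolites only.

    The first candidate (a higher-yield product route) is verified by LP to
    strictly improve the best double-knockout BPCY; the others are a
    respiration duplicate (re-opens the redox valve, detrimental after the
    coupling knockouts) and overflow duplicates (neutral).
    """
    if n_candidates < 1:
        raise DomainError("n_candidates must be >= 1")
    inf = 1000.0
    y_ins = insertion_yield  # stoichiometric yield of the beneficial route
    candidates: list[tuple[str, dict[str, float], tuple[float, float], str]] = [
        ("INS_prodx", {"pyr": -1, "nadh": -1, "prod": y_ins, "nad": 1},
         (0, inf), "gX1"),
        ("INS_resp", {"nadh": -1, "nad": 1}, (0, inf), "gX2"),
        ("INS_ovf", {"pyr": -1, "by1": 1}, (0, inf), "gX3"),
    ]
    k = 2
    while len(candidates) < n_candidates:
        candidates.append((f"INS_ovf{k}", {"pyr": -1, f"by{min(k, 2)}": 1},
                           (0, inf), f"gX{k + 2}"))
        k += 1
    candidates = candidates[:n_candidates]

    mets: list[str] = []
    for _, stoich, *_ in candidates:
        for m in stoich:
            if m not in mets:
                mets.append(m)
    S = np.zeros((len(mets), len(candidates)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_, stoich, *_rest) in enumerate(candidates):
        for m, coef in stoich.items():
            S[midx[m], j] = coef
    comp = {m: c for m, c in zip(model.metabolites, model.met_compartment)}
    databank = MetabolicModel(
        metabolites=mets,
        reactions=[c[0] for c in candidates],
        S=S,
        lb=np.array([c[2][0] for c in candidates], dtype=float),
        ub=np.array([c[2][1] for c in candidates], dtype=float),
        objective_reaction=None,
        gpr=[c[3] for c in candidates],
        subsystem=["Heterologous"] * len(candidates),
        met_compartment=[comp.get(m, "c") for m in mets],
        gene_ids=[c[3] for c in candidates],
    )

    # verify at generation time that the designed edge is beneficial
    ko = model.knock_out(["RESP1", "RESP2"])
    base = predict_fba(ko, TOY_RATES)
    with_edge = ko.copy()
    n0 = with_edge.n_reactions
    S2 = np.zeros((with_edge.n_metabolites, n0 + 1))
    S2[:, :n0] = with_edge.S
    for m, coef in candidates[0][1].items():
        S2[with_edge.met_index(m), n0] = coef
    boosted = MetabolicModel(
        metabolites=with_edge.metabolites,
        reactions=with_edge.reactions + [candidates[0][0]],
        S=S2,
        lb=np.append(with_edge.lb, 0.0),
        ub=np.append(with_edge.ub, inf),
        objective_reaction=with_edge.objective_reaction,
        gpr=with_edge.gpr + [candidates[0][3]],
        subsystem=with_edge.subsystem + ["Heterologous"],
        met_compartment=with_edge.met_compartment,
        gene_ids=with_edge.gene_ids,
    )
    better = predict_fba(boosted, TOY_RATES)
    base_bpcy = base.vP * base.mu / base.vS if base.vS else 0.0
    new_bpcy = better.vP * better.mu / better.vS if better.vS else 0.0
    if not new_bpcy > base_bpcy + 1e-6:
        raise DomainError(
            "databank generation failed its self-check: the designed edge "
            f"does not improve the optimum ({base_bpcy:.4f} -> {new_bpcy:.4f})"
        )
    return databank


def toy_ground_truth(model: MetabolicModel, rates: RateSpec = TOY_RATES) -> dict:
    """Hand-checkable LP facts about the toy model, computed fresh.

    Used as the sidecar ground truth written next to generated fixtures.
    """
    wt = predict_fba(model, rates)
    single = predict_fba(model.knock_out(["RESP1"]), rates)
    double = predict_fba(model.knock_out(["RESP1", "RESP2"]), rates)

    def _bpcy(p):
        return p.vP * p.mu / p.vS if p.feasible and p.vS > 0 else 0.0

    return {
        "rates": {"biomass": rates.biomass, "product": rates.product,
                  "substrate": rates.substrate},
        "optimal_pair": ["RESP1", "RESP2"],
        "mu_wildtype": wt.mu,
        "bpcy_wildtype": _bpcy(wt),
        "bpcy_single_knockout": _bpcy(single),
        "bpcy_optimal_pair": _bpcy(double),
        "mu_optimal_pair": double.mu,
    }


def brute_force_optimal(
    model: MetabolicModel,
    space: TargetSpace,
    k: int,
    fitness_fn: Callable[[InterventionSet], float],
    max_insertions: int = 0,
    max_combinations: int = 100_000,
) -> tuple[InterventionSet, float, list[tuple[InterventionSet, float]]]:
    """Exhaustive oracle: evaluate every deletion set of size <= k.

    With ``max_insertions`` > 0 the cross-product with every insertion
    subset up to that size is enumerated too. Refuses combinatorially large
    requests. Returns the optimum and the full (deterministically ordered)
    ranking.
    """
    n_del = sum(math.comb(space.NT, s) for s in range(k + 1))
    n_ins = sum(math.comb(space.NT_ins, s) for s in range(max_insertions + 1))
    if n_del * n_ins > max_combinations:
        raise DomainError(
            f"{n_del * n_ins} combinations exceed the guard of {max_combinations}"
        )
    ranking: list[tuple[InterventionSet, float]] = []
    ins_subsets = [
        combo
        for s in range(max_insertions + 1)
        for combo in itertools.combinations(space.insertion_targets, s)
    ]
    for s in range(k + 1):
        for dels in itertools.combinations(space.deletion_targets, s):
            for ins in ins_subsets:
                iset = resolve_interventions(set(dels), set(ins), space, model)
                ranking.append((iset, float(fitness_fn(iset))))
    ranking.sort(key=lambda t: (-t[1], t[0].I, t[0].sort_key()))
    best_set, best_F = ranking[0]
    return best_set, best_F, ranking
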