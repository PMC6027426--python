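"""In-memory constraint-based metabolic model and GPR logic.

The :class:`MetabolicModel` is the substrate of every LP in the package: a
stoichiometric matrix ``S`` (metabolite x reaction), per-reaction flux bounds
in mmol gDW^-1 h^-1, a biomass objective reaction, and per-reaction
gene-protein-reaction (GPR) boolean rules. GPR parsing and evaluation are
delegated to :mod:`cobra`, which implements the field-standard grammar
(``and`` / ``or``, case-insensitive, arbitrary nesting).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from cobra.core.gene import GPR

from .errors import ConfigurationError

__all__ = [
    "MetabolicModel",
    "gpr_genes",
    "gpr_eval",
    "reactions_silenced_by",
]

_GENE_TOKEN = re.compile(r"\b(?!and\b|or\b|AND\b|OR\b|And\b|Or\b)[A-Za-z0-9_.\-]+\b")


@lru_cache(maxsize=None)
def _parse_gpr(rule: str) -> GPR:
    return GPR.from_string(rule)


def gpr_genes(rule: str) -> tuple[str, ...]:
    """Gene identifiers of a GPR rule, in order of first appearance."""
    if not rule or not rule.strip():
        return ()
    valid = _parse_gpr(rule).genes
    seen: list[str] = []
    for tok in _GENE_TOKEN.findall(rule):
        if tok in valid and tok not in seen:
            seen.append(tok)
    return tuple(seen)


def gpr_eval(rule: str, knockouts: Iterable[str]) -> bool:
    """Evaluate a GPR rule with the given genes set to False.

    An empty rule evaluates True: reactions without gene association cannot
    be silenced by gene deletions.
    """
    if not rule or not rule.strip():
        return True
    return _parse_gpr(rule).eval(knockouts=set(knockouts))


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    ``S`` has one row per metabolite and one column per reaction; fluxes are
    bounded by ``lb <= v <= ub``. ``gene_groups`` maps lumped gene-unit names
    (created by :func:`evostrain.model_io.lump_genes`) back to their member
    genes.
    """

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective_reaction: Optional[str]
    gpr: list[str]
    subsystem: list[str]
    met_compartment: list[str]
    gene_ids: list[str]
    gene_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float).copy()
        self.ub = np.asarray(self.ub, dtype=float).copy()
        m, n = self.S.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ConfigurationError(
                f"S is {self.S.shape} but model has {len(self.metabolites)} "
                f"metabolites and {len(self.reactions)} reactions"
            )
        if len(self.lb) != n or len(self.ub) != n:
            raise ConfigurationError("bound vectors do not match reaction count")
        if np.any(self.lb > self.ub + 1e-12):
            bad = self.reactions[int(np.argmax(self.lb > self.ub))]
            raise ConfigurationError(f"lb > ub for reaction {bad!r}")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise ConfigurationError("gpr/subsystem lists do not match reaction count")
        if self.objective_reaction is not None and self.objective_reaction not in self.reactions:
            raise ConfigurationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        self._rxn_index = {r: i for i, r in enumerate(self.reactions)}
        self._met_index = {m_: i for i, m_ in enumerate(self.metabolites)}

    # -- lookups ---------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def rxn_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise ConfigurationError(f"unknown reaction id {rid!r}") from None

    def met_index(self, mid: str) -> int:
        try:
            return self._met_index[mid]
        except KeyError:
            raise ConfigurationError(f"unknown metabolite id {mid!r}") from None

    def genes_of(self, rid: str) -> tuple[str, ...]:
        return gpr_genes(self.gpr[self.rxn_index(rid)])

    def exchange_mask(self) -> np.ndarray:
        """Structural exchange detection: columns with a single nonzero entry."""
        return np.count_nonzero(self.S, axis=0) == 1

    def transport_mask(self) -> np.ndarray:
        """Reactions whose participating metabolites span >1 compartment."""
        out = np.zeros(self.n_reactions, dtype=bool)
        comps = np.asarray(self.met_compartment, dtype=object)
        for j in range(self.n_reactions):
            involved = comps[self.S[:, j] != 0]
            out[j] = len(set(involved)) > 1
        return out

    # -- derived models --------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective_reaction=self.objective_reaction,
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            met_compartment=list(self.met_compartment),
            gene_ids=list(self.gene_ids),
            gene_groups=dict(self.gene_groups),
        )

    def with_bounds(self, changes: dict[str, tuple[float, float]]) -> "MetabolicModel":
        out = self.copy()
        for rid, (lo, hi) in changes.items():
            j = out.rxn_index(rid)
            out.lb[j] = lo
            out.ub[j] = hi
        return out

    def knock_out(self, reaction_ids: Iterable[str]) -> "MetabolicModel":
        """Return a copy with the given reactions closed (lb = ub = 0)."""
        return self.with_bounds({rid: (0.0, 0.0) for rid in reaction_ids})

    def expand_gene_units(self, units: Iterable[str]) -> frozenset[str]:
        """Resolve lumped gene-unit names to the underlying gene ids."""
        genes: set[str] = set()
        stack = list(units)
        while stack:
            u = stack.pop()
            members = self.gene_groups.get(u)
            if members is None:
                genes.add(u)
            else:
                stack.extend(members)
        return frozenset(genes)


def reactions_silenced_by(
    model: MetabolicModel, gene_units: Sequence[str]
) -> frozenset[str]:
    """Translate simultaneous gene(-unit) deletions to reaction deletions.

    A reaction is silenced iff its GPR evaluates False with every decoded
    gene unit set to False. Unit names and their expanded member genes are
    both knocked out, so the translation works on lumped and unlumped GPRs
    alike. Reactions without a GPR are never silenced.
    """
    knockouts = model.expand_gene_units(gene_units) | set(gene_units)
    if not knockouts:
        return frozenset()
    silenced = []
    for rid, rule in zip(model.reactions, model.gpr):
        if rule and not gpr_eval(rule, knockouts):
            silenced.append(rid)
    return frozenset(silenced)
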