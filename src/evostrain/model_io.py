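"""Model I/O and preprocessing.

Reading/writing SBML is delegated to cobrapy, which transparently handles
SBML L3+FBC as well as legacy L2 dialects where flux bounds live in
kinetic-law parameters. Preprocessing mirrors what is usually done before a
combinatorial knockout search: removal of dead-end sink/source reactions and
FVA-blocked reactions, lumping of obligate enzyme-subunit genes, and
reduction of the deletion target space to gene-associated, non-exchange,
non-transport reactions outside a configurable set of excluded subsystems.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InfeasibleModelError
from .model import MetabolicModel, gpr_eval, gpr_genes
from .phenotype import ReferenceState, fba, fva

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSpace",
    "read_sbml",
    "write_sbml",
    "read_reference_fluxes",
    "compress_model",
    "lump_genes",
    "build_target_space",
    "merge_databank",
    "DEFAULT_EXCLUDED_SUBSYSTEMS",
]

#: Subsystems whose member reactions are not deletion targets. Matched
#: case-insensitively as substrings, since labels vary across model releases.
DEFAULT_EXCLUDED_SUBSYSTEMS: tuple[str, ...] = (
    "cell envelope biosynthesis",
    "membrane lipid metabolism",
    "murein biosynthesis",
    "trna charging",
    "glycerophospholipid metabolism",
)

#: FVA tolerance below which a reaction is considered blocked (solver noise).
BLOCKED_TOL = 1e-9


@dataclass
class TargetSpace:
    """Ordered candidate interventions the GA may draw from.

    ``deletion_targets`` holds reaction ids (reaction mode) or gene-unit
    names (gene mode; lumped units resolve through the model's
    ``gene_groups``). ``insertion_targets`` lists databank reaction ids that
    are present in the merged model with closed bounds;
    ``insertion_bounds`` holds the bounds an insertion opens them to.
    """

    deletion_targets: list[str]
    mode: str = "reaction"
    insertion_targets: list[str] = field(default_factory=list)
    insertion_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("reaction", "gene"):
            raise ConfigurationError(f"unknown target mode {self.mode!r}")
        if len(set(self.deletion_targets)) != len(self.deletion_targets):
            raise ConfigurationError("duplicate deletion targets")
        if len(set(self.insertion_targets)) != len(self.insertion_targets):
            raise ConfigurationError("duplicate insertion targets")
        if self.NT < 1:
            raise ConfigurationError("empty deletion target space")

    @property
    def NT(self) -> int:
        return len(self.deletion_targets)

    @property
    def NT_ins(self) -> int:
        return len(self.insertion_targets)


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _from_cobra(cm, require_objective: bool = True) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cm, array_type="dense")
    objective = None
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    if require_objective and objective is None:
        raise ConfigurationError("model declares no objective reaction")
    genes: list[str] = []
    for rxn in cm.reactions:
        for g in gpr_genes(rxn.gene_reaction_rule or ""):
            if g not in genes:
                genes.append(g)
    return MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=[r.id for r in cm.reactions],
        S=S,
        lb=np.array([r.lower_bound for r in cm.reactions], dtype=float),
        ub=np.array([r.upper_bound for r in cm.reactions], dtype=float),
        objective_reaction=objective,
        gpr=[r.gene_reaction_rule or "" for r in cm.reactions],
        subsystem=[r.subsystem or "" for r in cm.reactions],
        met_compartment=[m.compartment or "c" for m in cm.metabolites],
        gene_ids=genes,
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML export and cross-checks)."""
    import cobra

    cm = cobra.Model("evostrain_model")
    mets = [
        cobra.Metabolite(mid, compartment=comp)
        for mid, comp in zip(model.metabolites, model.met_compartment)
    ]
    cm.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid, lower_bound=float(model.lb[j]),
                           upper_bound=float(model.ub[j]))
        r.subsystem = model.subsystem[j]
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, r in enumerate(cm.reactions):
        col = model.S[:, j]
        r.add_metabolites({
            mets[i]: float(col[i]) for i in np.flatnonzero(col)
        })
        rule = model.gpr[j]
        if rule:
            r.gene_reaction_rule = rule
    if model.objective_reaction is not None:
        cm.objective = model.objective_reaction
    # subsystems are serialized as SUBSYSTEM notes (the COBRA convention the
    # reader maps back onto reaction.subsystem); SBML groups would do too,
    # but cobra keeps group members in a set, which makes the output order
    # nondeterministic
    for r in cm.reactions:
        if r.subsystem:
            r.notes["SUBSYSTEM"] = r.subsystem
    # gene order out of GPR parsing is set-based; sort for deterministic output
    cm.genes.sort(key=lambda g: g.id)
    return cm


def read_sbml(path: str | Path, require_objective: bool = True) -> MetabolicModel:
    """Read an SBML model (L3+FBC preferred; legacy L2 bounds accepted).

    ``require_objective=False`` is meant for databank models of candidate
    insertion reactions, which carry no biomass objective.
    """
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sbml_logger = logging.getLogger("cobra.io.sbml")
    old_level = sbml_logger.level
    try:
        # databank models legitimately carry no objective; silence the
        # reader's complaint about it
        sbml_logger.setLevel(logging.CRITICAL)
        cm = read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise FormatError(f"could not parse SBML file {path}: {exc}") from exc
    finally:
        sbml_logger.setLevel(old_level)
    return _from_cobra(cm, require_objective=require_objective)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_reference_fluxes(path: str | Path) -> ReferenceState:
    """Read a two-column (reaction_id, flux) CSV/TSV reference distribution."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (reaction_id, flux)")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):  # header row present
        df = df.iloc[1:]
    fluxes = {str(r): float(v) for r, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return ReferenceState(fluxes=fluxes)


def write_prediction_csv(model: MetabolicModel, v: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"reaction_id": model.reactions, "flux": v}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

def _drop_reactions(model: MetabolicModel, drop: set[str]) -> MetabolicModel:
    keep = [j for j, r in enumerate(model.reactions) if r not in drop]
    S = model.S[:, keep]
    met_keep = np.flatnonzero(np.count_nonzero(S, axis=1) > 0)
    return MetabolicModel(
        metabolites=[model.metabolites[i] for i in met_keep],
        reactions=[model.reactions[j] for j in keep],
        S=S[met_keep, :],
        lb=model.lb[keep],
        ub=model.ub[keep],
        objective_reaction=model.objective_reaction,
        gpr=[model.gpr[j] for j in keep],
        subsystem=[model.subsystem[j] for j in keep],
        met_compartment=[model.met_compartment[i] for i in met_keep],
        gene_ids=list(model.gene_ids),
        gene_groups=dict(model.gene_groups),
    )


def compress_model(model: MetabolicModel, tol: float = BLOCKED_TOL) -> MetabolicModel:
    """Remove dead-end sink/source reactions and FVA-blocked reactions.

    Sole reactions of unbalanced (single-reaction) metabolites are removed
    first; then reactions whose FVA range is [0, 0] within ``tol`` are
    deleted, iterating to a fixed point. The optimal objective value is
    asserted unchanged.
    """
    _, obj0, ok = fba(model)
    if not ok or obj0 <= tol:
        raise InfeasibleModelError("cannot compress an infeasible model")

    out = model
    # sink/source reactions of unbalanced metabolites: a metabolite touched
    # by exactly one (non-exchange) reaction pins that reaction's flux to 0
    changed = True
    while changed:
        changed = False
        exch = out.exchange_mask()
        touch = np.count_nonzero(out.S, axis=1)
        drop: set[str] = set()
        for i in np.flatnonzero(touch == 1):
            j = int(np.flatnonzero(out.S[i, :] != 0)[0])
            if not exch[j] and out.reactions[j] != out.objective_reaction:
                drop.add(out.reactions[j])
        if drop:
            logger.info("compress: removing %d dead-end reactions", len(drop))
            out = _drop_reactions(out, drop)
            changed = True

    while True:
        vmin, vmax = fva(out)
        blocked = (np.abs(vmin) < tol) & (np.abs(vmax) < tol)
        if not blocked.any():
            break
        drop = {out.reactions[j] for j in np.flatnonzero(blocked)
                if out.reactions[j] != out.objective_reaction}
        if not drop:
            break
        logger.info("compress: removing %d blocked reactions", len(drop))
        out = _drop_reactions(out, drop)

    _, obj1, ok1 = fba(out)
    if not ok1 or abs(obj1 - obj0) > 1e-6 * max(1.0, abs(obj0)):
        raise InfeasibleModelError(
            f"compression changed the optimum ({obj0:.9g} -> {obj1:.9g})"
        )
    return out


# ---------------------------------------------------------------------------
# GPR lumping
# ---------------------------------------------------------------------------

def _and_equivalent(rule: str, group: frozenset[str], max_genes: int = 14) -> bool:
    """True if the rule depends on ``group`` only through the AND of members."""
    genes = gpr_genes(rule)
    if len(genes) > max_genes:
        return False
    members = [g for g in genes if g in group]
    for ko_bits in itertools.product((False, True), repeat=len(genes)):
        ko = {g for g, dead in zip(genes, ko_bits) if dead}
        val = gpr_eval(rule, ko)
        # collapse: if any member is deleted, delete them all
        if ko & group:
            ko_all = ko | set(members)
        else:
            ko_all = ko
        if val != gpr_eval(rule, ko_all):
            return False
    return True


def lump_genes(model: MetabolicModel, max_genes_per_gpr: int = 14) -> MetabolicModel:
    """Lump genes that act as obligate AND-conjuncts (enzyme subunits).

    Genes occurring in exactly the same reactions are lumped into one gene
    unit iff every containing GPR is invariant under replacing the group by
    the conjunction of its members (verified exhaustively on the rule's
    truth table). GPR truth values over whole-unit knockouts are unchanged.
    """
    occurrence: dict[str, frozenset[int]] = {}
    for j, rule in enumerate(model.gpr):
        for g in gpr_genes(rule):
            occurrence[g] = occurrence.get(g, frozenset()) | {j}

    by_signature: dict[frozenset[int], list[str]] = {}
    for g, sig in occurrence.items():
        by_signature.setdefault(sig, []).append(g)

    out = model.copy()
    for sig, members in by_signature.items():
        if len(members) < 2:
            continue
        group = frozenset(members)
        if not all(_and_equivalent(model.gpr[j], group, max_genes_per_gpr)
                   for j in sig):
            continue
        unit = "__".join(sorted(members))
        for j in sig:
            rule = out.gpr[j]
            for g in members:
                rule = re.sub(rf"(?<![\w.\-]){re.escape(g)}(?![\w.\-])", unit, rule)
            out.gpr[j] = rule
        out.gene_groups[unit] = tuple(sorted(members))
        logger.info("lumped %s -> %s", sorted(members), unit)

    genes: list[str] = []
    for rule in out.gpr:
        for g in gpr_genes(rule):
            if g not in genes:
                genes.append(g)
    out.gene_ids = genes
    return out


# ---------------------------------------------------------------------------
# Target space
# ---------------------------------------------------------------------------

def _eligible_deletion_mask(
    model: MetabolicModel,
    excluded_subsystems: Sequence[str],
    extra_excluded_reactions: Iterable[str],
) -> np.ndarray:
    excl_sub = [s.lower() for s in excluded_subsystems]
    extra = set(extra_excluded_reactions)
    exch = model.exchange_mask()
    trans = model.transport_mask()
    mask = np.zeros(model.n_reactions, dtype=bool)
    for j, rid in enumerate(model.reactions):
        if rid in extra or exch[j] or trans[j]:
            continue
        if not model.gpr[j]:
            continue
        sub = model.subsystem[j].lower()
        if sub and any(pat in sub for pat in excl_sub):
            continue
        if rid == model.objective_reaction:
            continue
        mask[j] = True
    return mask


def build_target_space(
    model: MetabolicModel,
    mode: str = "reaction",
    excluded_subsystems: Sequence[str] = DEFAULT_EXCLUDED_SUBSYSTEMS,
    extra_excluded_reactions: Iterable[str] = (),
    insertion_targets: Optional[Sequence[str]] = None,
    insertion_bounds: Optional[dict[str, tuple[float, float]]] = None,
) -> TargetSpace:
    """Build the ordered deletion (and optional insertion) target space.

    Reactions without gene association, structural exchange reactions,
    cross-compartment transporters, and members of excluded subsystems are
    filtered out. In gene mode the targets are the gene units of the
    remaining reactions, in order of first appearance.
    """
    mask = _eligible_deletion_mask(model, excluded_subsystems, extra_excluded_reactions)
    if mode == "reaction":
        targets = [model.reactions[j] for j in np.flatnonzero(mask)]
    elif mode == "gene":
        targets = []
        for j in np.flatnonzero(mask):
            for g in gpr_genes(model.gpr[j]):
                if g not in targets:
                    targets.append(g)
    else:
        raise ConfigurationError(f"unknown target mode {mode!r}")
    if not targets:
        raise ConfigurationError(
            "target space is empty after filtering; relax the exclusion rules"
        )
    return TargetSpace(
        deletion_targets=targets,
        mode=mode,
        insertion_targets=list(insertion_targets or []),
        insertion_bounds=dict(insertion_bounds or {}),
    )


def merge_databank(
    model: MetabolicModel,
    databank: MetabolicModel,
    mode: str = "reaction",
    **target_space_kwargs,
) -> tuple[MetabolicModel, TargetSpace]:
    """Append candidate insertion reactions (closed) and build the target space.

    Only databank reactions whose metabolites all exist in the wild-type
    model are accepted (novel network edges, not novel pathways); others are
    logged and skipped. Accepted reactions enter with lb = ub = 0 and open to
    the databank's stated bounds when an individual selects them.
    """
    overlap = set(databank.reactions) & set(model.reactions)
    if overlap:
        raise ConfigurationError(
            f"databank reaction ids collide with the model: {sorted(overlap)[:5]}"
        )
    native = set(model.metabolites)
    accepted: list[int] = []
    for j, rid in enumerate(databank.reactions):
        mets = [databank.metabolites[i] for i in np.flatnonzero(databank.S[:, j])]
        foreign = [m for m in mets if m not in native]
        if foreign:
            logger.info("databank reaction %s rejected (foreign metabolites %s)",
                        rid, foreign)
            continue
        accepted.append(j)

    merged = model.copy()
    n_new = len(accepted)
    n0 = merged.n_reactions
    S_new = np.zeros((merged.n_metabolites, n0 + n_new))
    S_new[:, :n0] = merged.S
    ins_bounds: dict[str, tuple[float, float]] = {}
    for k, j in enumerate(accepted):
        rid = databank.reactions[j]
        for i in np.flatnonzero(databank.S[:, j]):
            S_new[merged.met_index(databank.metabolites[i]),
                  n0 + k] = databank.S[i, j]
        merged.reactions.append(rid)
        merged.gpr.append(databank.gpr[j])
        merged.subsystem.append(databank.subsystem[j])
        ins_bounds[rid] = (float(databank.lb[j]), float(databank.ub[j]))
    merged = MetabolicModel(
        metabolites=merged.metabolites,
        reactions=merged.reactions,
        S=S_new,
        lb=np.concatenate([merged.lb, np.zeros(n_new)]),
        ub=np.concatenate([merged.ub, np.zeros(n_new)]),
        objective_reaction=merged.objective_reaction,
        gpr=merged.gpr,
        subsystem=merged.subsystem,
        met_compartment=merged.met_compartment,
        gene_ids=merged.gene_ids,
        gene_groups=merged.gene_groups,
    )
    # insertion candidates are not deletion targets
    extra = set(target_space_kwargs.pop("extra_excluded_reactions", ()))
    extra |= set(ins_bounds)
    space = build_target_space(
        merged,
        mode=mode,
        extra_excluded_reactions=extra,
        insertion_targets=[databank.reactions[j] for j in accepted],
        insertion_bounds=ins_bounds,
        **target_space_kwargs,
    )
    return merged, space
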