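"""Balanced binary encoding of intervention targets and bit-genome individuals.

Each of the ND deletion slots of an individual is one binary number of NB
bits; every one of the 2^NB values is assigned to a target (blank values are
distributed back over the targets), in contiguous blocks whose sizes differ
by at most one. With the default bit-width rule every target owns at least
50 values, so the relative difference in per-target draw probability stays
below 2%. Insertion slots use an independent scheme sized from the number of
insertion candidates by the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError
from .model import MetabolicModel, reactions_silenced_by
from .model_io import TargetSpace

__all__ = [
    "bits_per_target",
    "build_value_map",
    "EncodingScheme",
    "GenomeSpec",
    "Individual",
    "InterventionSet",
    "decode",
    "resolve_interventions",
    "random_individual",
]

#: minimum number of binary values guaranteed per target (default mode)
MIN_VALUES_PER_TARGET = 50


def bits_per_target(NT: int, mode: str = "guaranteed",
                    min_values: int = MIN_VALUES_PER_TARGET) -> int:
    """Bits per slot so each of NT targets owns ~``min_values`` binary values.

    ``guaranteed`` (default) returns the smallest NB with 2^NB >= 50*NT, which
    actually delivers the >=50-values promise. ``literal`` applies
    round(log2(50*NT)) (round half away from zero), which can fall one bit
    short for some NT; it is kept for fidelity with the original rule.
    """
    if NT < 1:
        raise DomainError(f"NT must be >= 1, got {NT}")
    x = math.log2(min_values * NT)
    if mode == "literal":
        return int(math.floor(x + 0.5))
    if mode == "guaranteed":
        nb = int(math.ceil(x))
        while 2 ** nb < min_values * NT:  # guard against float fringe cases
            nb += 1
        return nb
    raise DomainError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class EncodingScheme:
    """Assignment of all 2^NB binary values to NT targets in balanced blocks."""

    NT: int
    NB: int
    block_sizes: tuple[int, ...]
    _starts: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def min_values_per_target(self) -> int:
        return min(self.block_sizes)

    @property
    def max_values_per_target(self) -> int:
        return max(self.block_sizes)

    def value_to_target(self, value: int) -> int:
        """Map a slot's binary value to its target index (total on [0, 2^NB))."""
        if not 0 <= value < 2 ** self.NB:
            raise DomainError(f"value {value} outside [0, 2^{self.NB})")
        return int(np.searchsorted(self._starts, value, side="right") - 1)

    def draw_probabilities(self) -> np.ndarray:
        """Per-target probability of a uniformly random slot value."""
        return np.array(self.block_sizes) / 2 ** self.NB


def build_value_map(NT: int, NB: int) -> EncodingScheme:
    """Balanced contiguous value blocks: sizes floor(2^NB/NT) or that plus one."""
    if NT < 1:
        raise DomainError(f"NT must be >= 1, got {NT}")
    total = 2 ** NB
    if total < NT:
        raise DomainError(f"2^{NB} = {total} values cannot cover {NT} targets")
    base, rem = divmod(total, NT)
    sizes = tuple([base + 1] * rem + [base] * (NT - rem))
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return EncodingScheme(NT=NT, NB=NB, block_sizes=sizes, _starts=starts)


@dataclass(frozen=True)
class GenomeSpec:
    """Fixed genome layout: ND deletion slots ++ NI insertion slots.

    Bits within a slot are most-significant first; crossover points fall on
    slot boundaries only.
    """

    ND: int
    NI: int
    del_scheme: EncodingScheme
    ins_scheme: Optional[EncodingScheme] = None

    def __post_init__(self) -> None:
        if self.ND < 1:
            raise DomainError("ND must be >= 1")
        if self.NI > 0 and self.ins_scheme is None:
            raise DomainError("NI > 0 requires an insertion scheme")

    @classmethod
    def for_space(cls, space: TargetSpace, ND: int, NI: int = 0,
                  mode: str = "guaranteed") -> "GenomeSpec":
        del_scheme = build_value_map(space.NT, bits_per_target(space.NT, mode))
        ins_scheme = None
        if NI > 0:
            if space.NT_ins < 1:
                raise DomainError("NI > 0 but the target space has no insertions")
            ins_scheme = build_value_map(space.NT_ins,
                                         bits_per_target(space.NT_ins, mode))
        return cls(ND=ND, NI=NI, del_scheme=del_scheme, ins_scheme=ins_scheme)

    @property
    def n_bits(self) -> int:
        nb = self.ND * self.del_scheme.NB
        if self.NI:
            nb += self.NI * self.ins_scheme.NB
        return nb

    @property
    def n_slots(self) -> int:
        return self.ND + self.NI

    def slot_boundaries(self) -> list[int]:
        """Bit offsets of the ND+NI-1 admissible crossover points."""
        cuts, pos = [], 0
        widths = [self.del_scheme.NB] * self.ND
        if self.NI:
            widths += [self.ins_scheme.NB] * self.NI
        for w in widths[:-1]:
            pos += w
            cuts.append(pos)
        return cuts

    def slot_values(self, bits: np.ndarray) -> tuple[list[int], list[int]]:
        nb = self.del_scheme.NB
        dvals = [
            int(np.dot(bits[k * nb:(k + 1) * nb],
                       2 ** np.arange(nb - 1, -1, -1)))
            for k in range(self.ND)
        ]
        ivals: list[int] = []
        if self.NI:
            off = self.ND * nb
            ni = self.ins_scheme.NB
            ivals = [
                int(np.dot(bits[off + k * ni:off + (k + 1) * ni],
                           2 ** np.arange(ni - 1, -1, -1)))
                for k in range(self.NI)
            ]
        return dvals, ivals

    def to_string(self, bits: np.ndarray) -> str:
        nb = self.del_scheme.NB
        parts = ["".join(map(str, bits[k * nb:(k + 1) * nb]))
                 for k in range(self.ND)]
        s = " ".join(parts)
        if self.NI:
            off = self.ND * nb
            ni = self.ins_scheme.NB
            parts = ["".join(map(str, bits[off + k * ni:off + (k + 1) * ni]))
                     for k in range(self.NI)]
            s += "|" + " ".join(parts)
        return s

    def from_string(self, s: str) -> np.ndarray:
        flat = s.replace("|", "").replace(" ", "")
        bits = np.fromiter((int(ch) for ch in flat), dtype=np.uint8)
        if len(bits) != self.n_bits:
            raise DomainError(
                f"genome string has {len(bits)} bits, expected {self.n_bits}"
            )
        return bits


@dataclass
class Individual:
    """A candidate design: a fixed-length bit genome plus a fitness cache."""

    bits: np.ndarray
    fitness: object | None = None

    def copy(self, keep_fitness: bool = True) -> "Individual":
        return Individual(self.bits.copy(), self.fitness if keep_fitness else None)

    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass(frozen=True)
class InterventionSet:
    """Unique network perturbations an individual decodes to.

    ``I`` counts unique targets (deletion targets plus insertions); in gene
    mode ``reaction_deletions`` holds the GPR-translated silenced reactions
    while ``gene_deletions`` holds the decoded gene units.
    """

    reaction_deletions: frozenset[str] = frozenset()
    gene_deletions: frozenset[str] = frozenset()
    insertions: frozenset[str] = frozenset()

    @property
    def I(self) -> int:  # noqa: E743 - the field's standard symbol
        n_del = len(self.gene_deletions) if self.gene_deletions else len(
            self.reaction_deletions)
        return n_del + len(self.insertions)

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.reaction_deletions)),
                tuple(sorted(self.gene_deletions)),
                tuple(sorted(self.insertions)))


def resolve_interventions(
    deletion_targets: "list[str] | set[str]",
    insertion_targets: "list[str] | set[str]",
    space: TargetSpace,
    model: MetabolicModel,
) -> InterventionSet:
    """Build an InterventionSet from decoded target names.

    In gene mode the gene units are translated to silenced reactions via the
    GPR logic of the model.
    """
    dels = frozenset(deletion_targets)
    ins = frozenset(insertion_targets)
    if space.mode == "gene":
        return InterventionSet(
            reaction_deletions=reactions_silenced_by(model, sorted(dels)),
            gene_deletions=dels,
            insertions=ins,
        )
    return InterventionSet(reaction_deletions=dels, insertions=ins)


def decode(
    individual: Individual,
    space: TargetSpace,
    spec: GenomeSpec,
    model: MetabolicModel,
) -> InterventionSet:
    """Decode a genome into its unique intervention set (duplicates collapse)."""
    dvals, ivals = spec.slot_values(individual.bits)
    dels = {space.deletion_targets[spec.del_scheme.value_to_target(v)]
            for v in dvals}
    ins = {space.insertion_targets[spec.ins_scheme.value_to_target(v)]
           for v in ivals}
    return resolve_interventions(dels, ins, space, model)


def random_individual(spec: GenomeSpec, rng: np.random.Generator) -> Individual:
    """Uniformly random genome: each bit 0/1 with probability one half."""
    return Individual(bits=rng.integers(0, 2, spec.n_bits, dtype=np.uint8))
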