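"""Canonical variant genotypes for a mutagenised ribozyme construct.

A :class:`Variant` is an ordered collection of :class:`Mutation` objects
expressed relative to a consensus construct.  Positions use the field's
ribozyme numbering: the cleavage-site G is position 1, the base immediately
5' of it is position -1, and there is no position 0.  A construct may carry
flanking linker nucleotides 5' of position 1; the length of that flank is
needed to convert between ribozyme positions and 0-based string indices.

Indels are canonicalised to the leftmost position of the homopolymer run
they fall in, so that sequence-identical molecules map to a single genotype
key (deleting either A of an AA run yields the same product).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

RNA_BASES = "ACGU"
WATSON_CRICK = {"A": "U", "U": "A", "G": "C", "C": "G"}

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"

_MUTATION_RE = re.compile(r"^([ACGU])(-?\d+)(del|ins|[ACGU])$")


def pos_to_index(position: int, flank: int = 0) -> int:
    """Map a ribozyme position (1-based, no zero; negatives 5' of the
    cleavage site) to a 0-based index into a construct with ``flank``
    upstream linker nucleotides."""
    if position == 0:
        raise ValueError("position 0 does not exist in ribozyme numbering")
    idx = flank + position - 1 if position > 0 else flank + position
    if idx < 0:
        raise ValueError(f"position {position} lies outside the {flank}-nt flank")
    return idx


def index_to_pos(index: int, flank: int = 0) -> int:
    """Inverse of :func:`pos_to_index`."""
    if index < 0:
        raise ValueError("negative index")
    off = index - flank
    return off + 1 if off >= 0 else off


@dataclass(frozen=True, order=True)
class Mutation:
    """One edit relative to the consensus construct.

    ``ref`` is the consensus base at ``position``; for substitutions ``alt``
    is the new base, for insertions the inserted base equals ``ref`` (a
    double incorporation), and for deletions ``alt`` is empty.
    """

    position: int
    kind: str
    ref: str
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (SUBSTITUTION, DELETION, INSERTION):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.ref not in RNA_BASES:
            raise ValueError(f"ref base {self.ref!r} not one of {RNA_BASES}")
        if self.kind == SUBSTITUTION:
            if self.alt not in RNA_BASES:
                raise ValueError(f"alt base {self.alt!r} not one of {RNA_BASES}")
            if self.alt == self.ref:
                raise ValueError("substitution must change the base")
        elif self.alt:
            raise ValueError(f"{self.kind} carries no alt base")

    @property
    def label(self) -> str:
        if self.kind == SUBSTITUTION:
            return f"{self.ref}{self.position}{self.alt}"
        suffix = "del" if self.kind == DELETION else "ins"
        return f"{self.ref}{self.position}{suffix}"

    @property
    def is_indel(self) -> bool:
        return self.kind != SUBSTITUTION


def parse_mutation(label: str) -> Mutation:
    m = _MUTATION_RE.match(label.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation label {label!r}")
    ref, pos, tail = m.group(1), int(m.group(2)), m.group(3)
    if tail == "del":
        return Mutation(pos, DELETION, ref)
    if tail == "ins":
        return Mutation(pos, INSERTION, ref)
    return Mutation(pos, SUBSTITUTION, ref, tail)


@dataclass(frozen=True)
class Variant:
    """A canonical genotype: a position-sorted tuple of mutations."""

    mutations: tuple[Mutation, ...] = ()

    @classmethod
    def from_mutations(cls, mutations: Iterable[Mutation]) -> "Variant":
        return cls(tuple(sorted(mutations)))

    @classmethod
    def from_label(cls, label: str) -> "Variant":
        label = label.strip()
        if label in ("", "consensus"):
            return cls()
        return cls.from_mutations(parse_mutation(tok) for tok in label.split(","))

    @property
    def label(self) -> str:
        if not self.mutations:
            return "consensus"
        return ",".join(m.label for m in self.mutations)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def is_consensus(self) -> bool:
        return not self.mutations

    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.mutations)

    def substitution_at(self, position: int) -> str | None:
        """The substituted base at ``position``, if any."""
        for m in self.mutations:
            if m.position == position and m.kind == SUBSTITUTION:
                return m.alt
        return None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


CONSENSUS = Variant()

#: Variant classes by mutation count.
CLASS_CONSENSUS = "consensus"
CLASS_SINGLE = "single"
CLASS_DOUBLE = "double"
CLASS_HIGHER = "higher-order"


def classify_variant(variant: Variant) -> tuple[str, frozenset[str]]:
    """Classify by mutation count and tag indel content.

    Returns ``(class, tags)`` where class is one of consensus/single/double/
    higher-order and tags may contain ``"deletion"``, ``"insertion"`` and the
    summary tag ``"indel"``.
    """
    n = variant.n_mutations
    if n == 0:
        cls = CLASS_CONSENSUS
    elif n == 1:
        cls = CLASS_SINGLE
    elif n == 2:
        cls = CLASS_DOUBLE
    else:
        cls = CLASS_HIGHER
    tags = set()
    for m in variant.mutations:
        if m.kind == DELETION:
            tags |= {"deletion", "indel"}
        elif m.kind == INSERTION:
            tags |= {"insertion", "indel"}
    return cls, frozenset(tags)


def _run_start(construct: str, idx: int) -> int:
    """Index of the first base of the homopolymer run containing ``idx``."""
    base = construct[idx]
    while idx > 0 and construct[idx - 1] == base:
        idx -= 1
    return idx


def canonicalize(
    mutations: Iterable[Mutation], construct: str, flank: int = 0
) -> Variant:
    """Canonicalise a mutation set against ``construct``.

    Substitutions are kept as-is (after checking the ref base).  Deletions
    and double-incorporation insertions inside a homopolymer run are moved to
    the leftmost position(s) of the run; several deletions in one run occupy
    the run's leftmost positions in order.  Duplicate mutations collapse.
    """
    subs: list[Mutation] = []
    dels: list[int] = []
    inss: list[int] = []
    for m in set(mutations):
        idx = pos_to_index(m.position, flank)
        if construct[idx] != m.ref:
            raise ValueError(
                f"mutation {m.label}: consensus has {construct[idx]} at "
                f"position {m.position}"
            )
        if m.kind == SUBSTITUTION:
            subs.append(m)
        elif m.kind == DELETION:
            dels.append(idx)
        else:
            inss.append(idx)

    canon: list[Mutation] = list(subs)
    # deletions: pack into the leftmost slots of each homopolymer run
    by_run: dict[int, int] = {}
    for idx in dels:
        start = _run_start(construct, idx)
        by_run[start] = by_run.get(start, 0) + 1
    for start, count in by_run.items():
        for k in range(count):
            idx = start + k
            canon.append(
                Mutation(index_to_pos(idx, flank), DELETION, construct[idx])
            )
    # insertions: one canonical site per run, multiplicity preserved is not
    # needed for doped synthesis (double incorporation happens at most once
    # per run in practice); collapse to the run start
    ins_runs = sorted({_run_start(construct, idx) for idx in inss})
    for start in ins_runs:
        canon.append(Mutation(index_to_pos(start, flank), INSERTION, construct[start]))
    return Variant.from_mutations(canon)


def apply_variant(construct: str, variant: Variant, flank: int = 0) -> str:
    """Mutated sequence produced by applying ``variant`` to ``construct``.

    Edits are applied from 3' to 5' so earlier indices stay valid; an
    insertion duplicates the consensus base immediately after its position.
    """
    seq = list(construct)
    # 3' to 5'; at a shared position substitutions apply before insertions so
    # the duplicate lands 5' of the substituted base
    order = sorted(
        variant.mutations, key=lambda m: (-m.position, m.kind != SUBSTITUTION)
    )
    for m in order:
        idx = pos_to_index(m.position, flank)
        if construct[idx] != m.ref:
            raise ValueError(f"{m.label}: consensus base mismatch")
        if m.kind == SUBSTITUTION:
            seq[idx] = m.alt
        elif m.kind == DELETION:
            del seq[idx]
        else:
            seq.insert(idx, m.ref)
    return "".join(seq)


def hamming_distance(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; unequal lengths are
    treated as infinitely distant (returned as a large sentinel)."""
    if len(a) != len(b):
        return max(len(a), len(b)) + 1
    return sum(x != y for x, y in zip(a, b))


def sort_key(variant: Variant) -> tuple:
    """Deterministic display order: position, then substitutions A<C<G<U,
    then deletion, then insertion (used for heatmap axes)."""
    kind_rank = {SUBSTITUTION: 0, DELETION: 1, INSERTION: 2}
    return tuple(
        (m.position, kind_rank[m.kind], m.alt) for m in variant.mutations
    )
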