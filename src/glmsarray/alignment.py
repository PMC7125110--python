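"""Pairwise global alignment utilities shared by genotype calling and the
conservation analysis.

Alignment uses Biopython's ``PairwiseAligner`` in global (Needleman-Wunsch)
mode with affine gap penalties; defaults follow common EMBOSS Needle usage
(match 5, mismatch -4, gap open 10, gap extend 0.5).  Ties are broken
deterministically by taking the aligner's first optimal alignment, which
prefers match/mismatch over gaps.
"""

from __future__ import annotations

from Bio import Align

from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Mutation,
    Variant,
    apply_variant,
    canonicalize,
    index_to_pos,
)

IUPAC_NT = set("ACGTURYSWKMBDHVN")


def normalize_rna(seq: str) -> str:
    """Uppercase, convert T to U, and reject non-IUPAC symbols."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - IUPAC_NT - {"U"}
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return s


def make_aligner(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    query: str,
    reference: str,
    aligner: Align.PairwiseAligner | None = None,
) -> Align.Alignment:
    """Optimal global alignment of ``query`` against ``reference`` (first
    optimal alignment under deterministic traceback order)."""
    if not query or not reference:
        raise ValueError("empty sequence")
    aligner = aligner or make_aligner()
    return aligner.align(normalize_rna(reference), normalize_rna(query))[0]


def aligned_columns(alignment: Align.Alignment) -> list[tuple[str, str]]:
    """(reference_symbol, query_symbol) per alignment column, gaps as '-'."""
    ref, qry = str(alignment[0]), str(alignment[1])
    return list(zip(ref, qry))


def genotype_from_sequence(
    sequence: str,
    consensus: str,
    flank: int = 0,
    aligner: Align.PairwiseAligner | None = None,
) -> Variant:
    """Call a canonical genotype for ``sequence`` relative to ``consensus``.

    Equal-length sequences are compared positionally; length-changing (or
    heavily substituted equal-length) sequences are aligned globally and the
    call with the fewest mutations wins, which collapses sequence-identical
    genotypes (e.g. a substitution+deletion pair that mimics a shifted
    deletion) onto one canonical key.  Insertions are supported only as
    double incorporations (a duplicate of an adjacent consensus base), the
    only insertion class doped synthesis produces.
    """
    sequence = normalize_rna(sequence)
    consensus = normalize_rna(consensus)
    candidates: list[Variant] = []
    if len(sequence) == len(consensus):
        muts = [
            Mutation(index_to_pos(i, flank), SUBSTITUTION, r, q)
            for i, (r, q) in enumerate(zip(consensus, sequence))
            if r != q
        ]
        positional = canonicalize(muts, consensus, flank)
        if positional.n_mutations <= 3:
            return positional
        candidates.append(positional)
    try:
        candidates.append(_genotype_by_alignment(sequence, consensus, flank, aligner))
    except ValueError:
        pass
    if not candidates:
        raise ValueError("could not call a genotype for the sequence")
    return min(candidates, key=lambda v: (v.n_mutations, v.label))


def _strict_column_call(
    ref: str, qry: str, consensus: str, flank: int
) -> Variant:
    """Call a genotype from aligned strings; raises when an insertion is not
    a double incorporation (duplicate of an adjacent consensus base)."""
    muts: list[Mutation] = []
    ref_i = 0
    for r, q in zip(ref, qry):
        if r != "-" and q != "-":
            if r != q:
                muts.append(Mutation(index_to_pos(ref_i, flank), SUBSTITUTION, r, q))
            ref_i += 1
        elif q == "-":  # deletion in the read
            muts.append(Mutation(index_to_pos(ref_i, flank), DELETION, r))
            ref_i += 1
        else:  # insertion in the read
            left = consensus[ref_i - 1] if ref_i > 0 else None
            right = consensus[ref_i] if ref_i < len(consensus) else None
            if q == left:
                pos = index_to_pos(ref_i - 1, flank)
            elif q == right:
                pos = index_to_pos(ref_i, flank)
            else:
                raise ValueError(
                    f"insertion of {q} at consensus index {ref_i} is not a "
                    "double incorporation"
                )
            muts.append(Mutation(pos, INSERTION, q))
    variant = canonicalize(muts, consensus, flank)
    # a valid call must reproduce the read exactly (guards against
    # position-ambiguous insertion/substitution interactions)
    if apply_variant(consensus, variant, flank) != qry.replace("-", ""):
        raise ValueError("genotype call does not reproduce the sequence")
    return variant


def _shift_gap(s: str, i: int, j: int) -> str:
    """Move the gap at index ``i`` to index ``j`` (letters in between shift)."""
    chars = list(s)
    del chars[i]
    chars.insert(j, "-")
    return "".join(chars)


def _genotype_by_alignment(
    sequence: str,
    consensus: str,
    flank: int,
    aligner: Align.PairwiseAligner | None,
    max_gap_shift: int = 4,
) -> Variant:
    aln = align_pair(sequence, consensus, aligner)
    ref, qry = str(aln[0]), str(aln[1])
    candidates: list[Variant] = []
    try:
        candidates.append(_strict_column_call(ref, qry, consensus, flank))
    except ValueError:
        pass
    # the aligner's gap placement is one of several equal-cost choices; some
    # are not double-incorporation-compatible and some imply extra
    # substitutions — slide each reference gap within a small window and
    # keep the call with the fewest mutations
    if "-" in ref:
        gaps = [i for i, ch in enumerate(ref) if ch == "-"]
        for i in gaps:
            for delta in range(-max_gap_shift, max_gap_shift + 1):
                j = i + delta
                if delta == 0 or not 0 <= j < len(ref) or ref[j] == "-":
                    continue
                try:
                    candidates.append(
                        _strict_column_call(_shift_gap(ref, i, j), qry, consensus, flank)
                    )
                except ValueError:
                    continue
    if not candidates:
        raise ValueError("no double-incorporation-compatible alignment found")
    return min(candidates, key=lambda v: (v.n_mutations, v.label))
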