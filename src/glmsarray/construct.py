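"""Default core-ribozyme construct used by the simulator and examples.

The 66-nt core sequence below is a SYNTHETIC stand-in: it is not a natural
glmS ribozyme, but it reproduces the architecture the pipeline operates on —
the duplex elements P1, P2, P2.1 and P2.2 of the core double pseudoknot, the
bulged A6, the catalytically essential residues around the cleavage
dinucleotide A(-1)G1, and every residue identity referenced elsewhere in the
package (e.g. the ten non-cleaving reference mutants used for tile
normalization).  Position 1 is the cleavage-site G; the 5-nt linker AUAAA
upstream supplies A(-1).
"""

from __future__ import annotations

from .variants import Variant, WATSON_CRICK, pos_to_index

#: Synthetic 66-nt core consensus (positions 1..66 in ribozyme numbering).
CORE_CONSENSUS = (
    "GCGCCAGAAC"  # 1-10
    "GCGAAACAAA"  # 11-20
    "GCGUUGACGC"  # 21-30
    "UAAGGAGGUA"  # 31-40
    "ACGCGAACAU"  # 41-50
    "ACGGCGGAAC"  # 51-60
    "CCUCCU"      # 61-66
)

FIVE_PRIME_FLANK = "AUAAA"
THREE_PRIME_FLANK = "AAA"
FLANK = len(FIVE_PRIME_FLANK)

#: Full transcribed construct: linker + core + linker.
FULL_CONSTRUCT = FIVE_PRIME_FLANK + CORE_CONSENSUS + THREE_PRIME_FLANK

#: Watson-Crick duplex elements of the core pseudoknot, as (5' pos, 3' pos)
#: basepairs in ribozyme numbering.  A6 is bulged out of P2.2.
DUPLEXES: dict[str, tuple[tuple[int, int], ...]] = {
    "P2.2": ((2, 56), (3, 55), (4, 54), (5, 53), (7, 52)),
    "P1": ((8, 25), (9, 24), (10, 23), (11, 22), (12, 21)),
    "P2.1": ((28, 45), (29, 44), (30, 43)),
    "P2": ((33, 66), (34, 65), (35, 64), (36, 63), (37, 62), (38, 61)),
}

#: Positions whose base identity is required for catalysis or cofactor
#: binding beyond any duplex role (cleavage site, active-site residues,
#: binding-pocket residues).
CATALYTIC_POSITIONS: frozenset[int] = frozenset({1, 2, 3, 26, 27, 28, 45, 52, 56, 57})

#: The ten non-cleaving single mutants used as the per-tile normalization
#: reference set.
REFERENCE_NONCLEAVER_LABELS: tuple[str, ...] = (
    "G1C", "G1U", "C2G", "C2A", "G3C", "A27G", "C28G", "G56C", "G56U", "G57C",
)

REFERENCE_NONCLEAVERS: tuple[Variant, ...] = tuple(
    Variant.from_label(lbl) for lbl in REFERENCE_NONCLEAVER_LABELS
)

#: Doped interval of the construct (0-based, half-open, full-construct
#: coordinates): the whole 66-nt core ...
DOPED_REGION: tuple[int, int] = (FLANK, FLANK + len(CORE_CONSENSUS))

#: ... minus the top half of the P1 hairpin (positions 11-22: the upper stem
#: and loop), leaving 54 doped positions.
EXCLUDED_INDICES: frozenset[int] = frozenset(
    pos_to_index(p, FLANK) for p in range(11, 23)
)


def paired_position(position: int) -> int | None:
    """The Watson-Crick partner of ``position`` in the designed duplexes."""
    for pairs in DUPLEXES.values():
        for p, q in pairs:
            if position == p:
                return q
            if position == q:
                return p
    return None


def _check() -> None:
    for name, pairs in DUPLEXES.items():
        for p, q in pairs:
            b5 = CORE_CONSENSUS[p - 1]
            b3 = CORE_CONSENSUS[q - 1]
            if WATSON_CRICK[b5] != b3:
                raise AssertionError(f"{name} pair {p}-{q}: {b5}/{b3} not WC")
    for v in REFERENCE_NONCLEAVERS:
        m = v.mutations[0]
        if CORE_CONSENSUS[m.position - 1] != m.ref:
            raise AssertionError(f"reference mutant {m.label} ref mismatch")


_check()
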