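"""Barcode grouping, consensus calling, and cluster-to-variant assignment.

Reads sharing a 16-nt barcode are clonal copies of one library molecule.
The consensus sequence of a barcode group is the modal base at each
position; a group is kept only when every position is both consistent (at
least 66% of reads match the modal base) and statistically non-random (the
one-sided binomial tail probability of the modal count under a uniform
null, success probability 0.25, is below 0.05).  Downstream, a cluster's
read is assigned to its barcode's variant when its Hamming distance to the
barcode consensus is below three.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import genotype_from_sequence
from .variants import Variant, hamming_distance

ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
UNKNOWN_BARCODE = "unknown_barcode"


@dataclass
class BarcodeGroup:
    """Consensus-call result for the reads of one barcode."""

    barcode: str
    reads: tuple[str, ...]
    modal_sequence: str
    kept: bool
    match_fractions: np.ndarray
    p_values: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def consensus(self) -> str | None:
        """Defined only for kept groups."""
        return self.modal_sequence if self.kept else None


def binomial_tail_p(count: int, n: int, p: float = 0.25) -> float:
    """One-sided upper-tail binomial probability P(X >= count)."""
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    return float(stats.binom.sf(count - 1, n, p))


def call_consensus(
    reads: Sequence[str],
    min_match_fraction: float = 0.66,
    alpha: float = 0.05,
    barcode: str = "",
) -> BarcodeGroup:
    """Call the per-barcode consensus and apply the keep filters.

    The positional vote runs in the group's own frame: the modal read
    length.  Reads of deviant length do not vote but still count in the
    match-fraction denominator, so a barcode whose reads disagree in length
    is penalised accordingly.
    """
    if not reads:
        raise ValueError("empty read set")
    lengths = Counter(len(r) for r in reads)
    frame_len = min(
        (l for l, c in lengths.items() if c == max(lengths.values()))
    )  # modal length; ties broken toward the shorter frame
    voters = [r for r in reads if len(r) == frame_len]
    n_total = len(reads)

    consensus_chars: list[str] = []
    fractions = np.empty(frame_len)
    p_values = np.empty(frame_len)
    for j in range(frame_len):
        column = Counter(r[j] for r in voters)
        modal_count = max(column.values())
        modal_base = min(b for b, c in column.items() if c == modal_count)
        consensus_chars.append(modal_base)
        fractions[j] = modal_count / n_total
        p_values[j] = binomial_tail_p(modal_count, len(voters))

    kept = bool(
        np.all(fractions >= min_match_fraction) and np.all(p_values < alpha)
    )
    return BarcodeGroup(
        barcode=barcode,
        reads=tuple(reads),
        modal_sequence="".join(consensus_chars),
        kept=kept,
        match_fractions=fractions,
        p_values=p_values,
    )


def build_consensus_map(
    read_table: pd.DataFrame,
    min_match_fraction: float = 0.66,
    alpha: float = 0.05,
) -> tuple[dict[str, BarcodeGroup], pd.DataFrame]:
    """Group a (barcode, sequence) table by barcode and call each group.

    Returns the per-barcode groups and a summary table
    (barcode, consensus, kept, n_reads)."""
    groups: dict[str, BarcodeGroup] = {}
    for barcode, sub in read_table.groupby("barcode", sort=True):
        groups[barcode] = call_consensus(
            list(sub["sequence"]), min_match_fraction, alpha, barcode=barcode
        )
    summary = pd.DataFrame(
        {
            "barcode": list(groups),
            "consensus": [g.consensus or "" for g in groups.values()],
            "kept": [g.kept for g in groups.values()],
            "n_reads": [g.n_reads for g in groups.values()],
        }
    )
    return groups, summary


def assign_variant(
    sequence: str,
    barcode: str,
    consensus_map: Mapping[str, BarcodeGroup],
    hamming_max: int = 2,
) -> tuple[str, str | None]:
    """Assign a cluster read to its barcode consensus.

    Returns ``(status, consensus_sequence)``; status is ``assigned`` when the
    Hamming distance (equal-length comparison) is <= ``hamming_max``,
    ``unassigned`` otherwise, and ``unknown_barcode`` when the barcode has no
    kept consensus.
    """
    group = consensus_map.get(barcode)
    if group is None or not group.kept:
        return UNKNOWN_BARCODE, None
    if hamming_distance(sequence, group.modal_sequence) <= hamming_max:
        return ASSIGNED, group.modal_sequence
    return UNASSIGNED, None


def assign_clusters(
    cluster_table: pd.DataFrame,
    consensus_map: Mapping[str, BarcodeGroup],
    consensus_construct: str,
    flank: int = 0,
    hamming_max: int = 2,
) -> pd.DataFrame:
    """Annotate a cluster table with assignment status and variant genotype.

    The genotype is called once per distinct barcode-consensus sequence by
    comparison/alignment against the consensus construct.
    """
    genotype_cache: dict[str, str] = {}

    def genotype(seq: str) -> str:
        if seq not in genotype_cache:
            try:
                genotype_cache[seq] = genotype_from_sequence(
                    seq, consensus_construct, flank
                ).label
            except ValueError:
                genotype_cache[seq] = ""
        return genotype_cache[seq]

    statuses, labels = [], []
    for barcode, seq in zip(cluster_table["barcode"], cluster_table["sequence"]):
        status, cons = assign_variant(seq, barcode, consensus_map, hamming_max)
        if status == ASSIGNED:
            label = genotype(cons)
            if not label and cons is not None:
                status = UNASSIGNED
        else:
            label = ""
        statuses.append(status)
        labels.append(label)
    out = cluster_table.copy()
    out["assignment_status"] = statuses
    out["variant"] = labels
    return out
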