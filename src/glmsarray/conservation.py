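"""Per-base conservation from homolog alignments, and its correlation with
kinetic parameters.

Homolog sequences are globally aligned to the core consensus
(Needleman-Wunsch with affine gaps).  At each consensus position the
mutation frequency of each alternative base (and of gaps) is the count of
that mutation divided by the number of sequences with data at the position;
terminal gaps count as missing data, internal gaps count as deletions.
Rank correlation between per-mutation frequency and a kinetic parameter
uses Spearman's rho with the two-tailed p-value from the t-transform
t = rho sqrt((n-2)/(1-rho^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import align_pair, aligned_columns, make_aligner, normalize_rna
from .variants import RNA_BASES

align_to_consensus = align_pair  # domain-facing alias: (homolog, consensus)


def per_position_symbols(
    alignment, consensus_len: int
) -> list[str | None]:
    """Homolog symbol at each consensus position: a base, '-' for an
    internal gap, or None for missing data (terminal gaps)."""
    cols = aligned_columns(alignment)
    symbols: list[str | None] = []
    ref_i = 0
    for r, q in cols:
        if r == "-":
            continue  # insertion in the homolog: no consensus position
        symbols.append(q if q != "-" else "-")
        ref_i += 1
    assert len(symbols) == consensus_len
    # convert terminal gap runs to missing data
    i = 0
    while i < consensus_len and symbols[i] == "-":
        symbols[i] = None
        i += 1
    i = consensus_len - 1
    while i >= 0 and symbols[i] == "-":
        symbols[i] = None
        i -= 1
    return symbols


@dataclass
class ConservationRecord:
    """Mutation frequencies at one consensus position."""

    position: int  # ribozyme numbering (1-based in the core)
    consensus_base: str
    n_sequences: int
    f_mut: dict[str, float]  # per alternative base and "-" (deletion)
    f_mut_total: float


def mutation_frequency(
    homologs: Iterable[str],
    consensus: str,
    aligner=None,
) -> pd.DataFrame:
    """Align homologs to the consensus and tabulate per-base mutation
    frequencies.

    Returns one row per consensus position with columns ``position``,
    ``consensus_base``, ``n_seqs``, ``f_A`` .. ``f_U``, ``f_del`` and
    ``f_mut_total``.
    """
    consensus = normalize_rna(consensus)
    aligner = aligner or make_aligner()
    L = len(consensus)
    counts = np.zeros((L, len(RNA_BASES) + 1), dtype=int)  # bases + gap
    n_data = np.zeros(L, dtype=int)
    n_seqs = 0
    for seq in homologs:
        n_seqs += 1
        aln = align_pair(seq, consensus, aligner)
        symbols = per_position_symbols(aln, L)
        for i, sym in enumerate(symbols):
            if sym is None:
                continue
            n_data[i] += 1
            if sym == "-":
                counts[i, -1] += 1
            elif sym in RNA_BASES:
                counts[i, RNA_BASES.index(sym)] += 1
            # ambiguity codes count as data but not as a scored mutation
    if n_seqs == 0:
        raise ValueError("no homolog sequences supplied")
    rows = []
    for i in range(L):
        ref = consensus[i]
        denom = max(n_data[i], 1)
        f = {}
        for b in RNA_BASES:
            if b == ref:
                continue
            f[b] = counts[i, RNA_BASES.index(b)] / denom
        f["del"] = counts[i, -1] / denom
        rows.append(
            {
                "position": i + 1,
                "consensus_base": ref,
                "n_seqs": int(n_data[i]),
                **{f"f_{b}": f.get(b, 0.0) for b in RNA_BASES},
                "f_del": f["del"],
                "f_mut_total": float(sum(f.values())),
            }
        )
    df = pd.DataFrame(rows)
    for b in RNA_BASES:  # frequency of the consensus base itself is retention
        df.loc[df["consensus_base"] == b, f"f_{b}"] = np.nan
    return df


def single_mutant_frequency(freq: pd.DataFrame, label: str) -> float:
    """f_mut of one point substitution (e.g. ``G7C``: base C at position 7)."""
    ref, pos, alt = label[0], int(label[1:-1]), label[-1]
    row = freq.loc[freq["position"] == pos]
    if row.empty or row["consensus_base"].iloc[0] != ref:
        raise KeyError(f"no conservation record matching {label}")
    return float(row[f"f_{alt}"].iloc[0])


@dataclass
class CorrelationResult:
    """Spearman rank correlation of f_mut against one kinetic parameter."""

    parameter: str
    rho: float
    p_value: float
    n: int

    def summary(self) -> str:
        return (
            f"{self.parameter}: Spearman rho = {self.rho:.3f}, "
            f"two-tailed P = {self.p_value:.3g} (n = {self.n})"
        )


def spearman_rho_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with a two-tailed p from the t-distribution transform
    t = rho sqrt((n-2)/(1-rho^2)); rho is NaN for constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def correlate_conservation(
    f_mut: Mapping[str, float],
    kinetic: Mapping[str, float],
    parameter: str = "k_cat",
) -> CorrelationResult:
    """Correlate per-mutant conservation with a kinetic parameter.

    Pairing is by identical mutation identity (position + base change):
    only labels present in both maps with finite values enter.
    """
    labels = sorted(
        l
        for l in f_mut
        if l in kinetic
        and math.isfinite(f_mut[l])
        and math.isfinite(kinetic[l])
    )
    if len(labels) < 3:
        raise ValueError("fewer than 3 paired observations")
    x = [f_mut[l] for l in labels]
    y = [kinetic[l] for l in labels]
    rho, p = spearman_rho_p(x, y)
    return CorrelationResult(parameter, rho, p, len(labels))
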