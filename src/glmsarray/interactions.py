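"""Double-mutant rescue analysis and heatmap construction.

Under independence, a double mutant's rate reduction is the product of its
constituent single mutants' reductions.  A double mutant (i, j) that cleaves
faster than a constituent single j — rescue ratio k_obs(i,j)/k_obs(j) > 1 —
signals a mutational interaction.  The heatmap stores max(ratio, 1) so that
non-rescues form a background of 1, and a rescue is flagged significant only
when the two rates are separated by at least one sigma (the single mutant's
error, falling back to the double's when the single's error is undetermined
or its rate sits at/below the detection floor).

Compensatory basepair doubles rescue both constituent singles, producing
anti-diagonal bands in the rescue matrix from which duplex elements can be
read off; :func:`infer_duplexes` automates that read-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (
    SUBSTITUTION,
    Variant,
    WATSON_CRICK,
    classify_variant,
    sort_key,
)

classify_variant = classify_variant  # re-exported: classification lives with Variant


def expected_independent_rate(
    k_single_i: float, k_single_j: float, k_consensus: float
) -> float:
    """Independence expectation: k_cons * (k_i/k_cons) * (k_j/k_cons)."""
    if min(k_single_i, k_single_j, k_consensus) <= 0:
        raise ValueError("rates must be positive")
    return k_consensus * (k_single_i / k_consensus) * (k_single_j / k_consensus)


@dataclass
class RescueEntry:
    """Rescue of reference single j by second-site mutation i."""

    second_site: str  # single-mutant label i
    reference: str  # single-mutant label j
    double: str  # double-mutant label (i, j)
    ratio: float  # k_obs(i,j) / k_obs(j)
    heatmap_value: float  # max(ratio, 1)
    significant: bool
    sigma_used: str  # "single" or "double"
    fold_vs_consensus: float  # k_obs(i,j) / k_obs(consensus)


def compute_rescue(
    k_double: float,
    sigma_double: float,
    k_single_j: float,
    sigma_single_j: float,
    floor: float = 1e-6,
) -> tuple[float, float, bool, str]:
    """Rescue ratio, heatmap value, significance, and which sigma was used.

    Significance requires |k_double - k_single| >= 1 sigma, where sigma is
    the single mutant's rate error unless that error is unavailable or the
    single's rate is at/below the detection ``floor``, in which case the
    double's error is used.
    """
    if k_double <= 0 or k_single_j <= 0:
        raise ValueError("rates must be positive")
    ratio = k_double / k_single_j
    use_double = (
        not (math.isfinite(sigma_single_j) and sigma_single_j > 0)
        or k_single_j <= floor
    )
    sigma = sigma_double if use_double else sigma_single_j
    significant = bool(
        math.isfinite(sigma) and abs(k_double - k_single_j) >= sigma
    )
    return ratio, max(ratio, 1.0), significant, "double" if use_double else "single"


def _constituent_singles(double: Variant) -> tuple[Variant, Variant]:
    m1, m2 = double.mutations
    return Variant.from_mutations([m1]), Variant.from_mutations([m2])


def build_rescue_table(
    rates: Mapping[str, tuple[float, float]],
    floor: float = 1e-6,
) -> pd.DataFrame:
    """All rescue entries derivable from a {variant label: (k_obs, sigma)}
    rate map at one ligand concentration.

    Every double mutant whose two constituent singles are present yields two
    entries (each single once as the reference j).  Missing fits simply
    produce no entry.
    """
    k_cons = rates.get("consensus", (math.nan, math.nan))[0]
    entries: list[RescueEntry] = []
    for label, (k_d, s_d) in rates.items():
        v = Variant.from_label(label)
        if v.n_mutations != 2:
            continue
        for i, j in zip(_constituent_singles(v), _constituent_singles(v)[::-1]):
            if j.label not in rates:
                continue
            k_j, s_j = rates[j.label]
            if not (k_d > 0 and k_j > 0):
                continue
            ratio, hval, sig, which = compute_rescue(k_d, s_d, k_j, s_j, floor)
            entries.append(
                RescueEntry(
                    second_site=i.label,
                    reference=j.label,
                    double=label,
                    ratio=ratio,
                    heatmap_value=hval,
                    significant=sig,
                    sigma_used=which,
                    fold_vs_consensus=k_d / k_cons if k_cons and k_cons > 0 else math.nan,
                )
            )
    columns = [
        "second_site", "reference", "double", "ratio", "heatmap_value",
        "significant", "sigma_used", "fold_vs_consensus",
    ]
    return pd.DataFrame([e.__dict__ for e in entries], columns=columns)


def single_mutant_order(labels: Iterable[str]) -> list[str]:
    """Heatmap axis order: position, then substitution alt base A<C<G<U,
    then deletion, then insertion."""
    singles = [Variant.from_label(l) for l in labels]
    return [v.label for v in sorted(singles, key=sort_key)]


def rescue_matrix(
    rescue_table: pd.DataFrame,
    order: Sequence[str] | None = None,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Wide rescue heatmap: second-site i rows x reference j columns,
    background 1.  Non-significant rescues are set to background unless
    ``significant_only`` is False."""
    if order is None:
        labels = set(rescue_table.get("second_site", [])) | set(
            rescue_table.get("reference", [])
        )
        order = single_mutant_order(labels)
    mat = pd.DataFrame(1.0, index=list(order), columns=list(order))
    for _, row in rescue_table.iterrows():
        if row["second_site"] not in mat.index or row["reference"] not in mat.columns:
            continue
        value = row["heatmap_value"]
        if significant_only and not row["significant"]:
            value = 1.0
        mat.loc[row["second_site"], row["reference"]] = value
    mat.index.name = "second_site"
    mat.columns.name = "reference"
    return mat


def rate_matrix(
    rates: Mapping[str, tuple[float, float]],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Companion rate heatmap: M[i, j] = k_obs of the double (i, j); the
    diagonal carries the single-mutant rates."""
    singles = [l for l in rates if Variant.from_label(l).n_mutations == 1]
    if order is None:
        order = single_mutant_order(singles)
    mat = pd.DataFrame(math.nan, index=list(order), columns=list(order))
    for label in order:
        if label in rates:
            mat.loc[label, label] = rates[label][0]
    for label, (k, _s) in rates.items():
        v = Variant.from_label(label)
        if v.n_mutations != 2:
            continue
        a, b = _constituent_singles(v)
        if a.label in mat.index and b.label in mat.columns:
            mat.loc[a.label, b.label] = k
            mat.loc[b.label, a.label] = k
    mat.index.name = "first_mutation"
    mat.columns.name = "second_mutation"
    return mat


def infer_duplexes(
    rescue_table: pd.DataFrame,
    consensus_core: str,
    min_ratio: float = 2.0,
    min_run: int = 3,
) -> list[tuple[tuple[int, int], ...]]:
    """Read duplex elements off the rescue matrix's anti-diagonal bands.

    A position pair (p, q) is supported when some double mutant with
    substitutions at p and q restores Watson-Crick complementarity and
    significantly rescues BOTH constituent singles with ratio > ``min_ratio``.
    A duplex call is a maximal run (p, q), (p+1, q-1), ... of supported
    pairs of length >= ``min_run``.
    """
    if rescue_table.empty:
        return []
    support_counts: dict[tuple[int, int], set[str]] = {}
    for _, row in rescue_table.iterrows():
        if not row["significant"] or row["ratio"] <= min_ratio:
            continue
        double = Variant.from_label(row["double"])
        m1, m2 = double.mutations
        if m1.kind != SUBSTITUTION or m2.kind != SUBSTITUTION:
            continue
        p, q = m1.position, m2.position
        if p > q:
            (p, q), (m1, m2) = (q, p), (m2, m1)
        if p < 1 or q > len(consensus_core) or p == q:
            continue
        if WATSON_CRICK[m1.alt] != m2.alt:
            continue
        support_counts.setdefault((p, q), set()).add(row["reference"])
    # require rescue observed against both references
    supported = {
        pq for pq, refs in support_counts.items() if len(refs) >= 2
    }
    duplexes = []
    seen: set[tuple[int, int]] = set()
    for p, q in sorted(supported):
        if (p, q) in seen:
            continue
        run = []
        a, b = p, q
        while (a, b) in supported and a < b:
            run.append((a, b))
            seen.add((a, b))
            a, b = a + 1, b - 1
        if len(run) >= min_run:
            duplexes.append(tuple(run))
    return duplexes


def plot_rescue_heatmap(matrix: pd.DataFrame, path=None, log_scale: bool = True):
    """Optional matplotlib rendering of a rescue (or rate) matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.to_numpy(float)
    if log_scale:
        data = np.log10(np.clip(data, 1e-12, None))
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(data, cmap="viridis", origin="upper", aspect="auto")
    ax.set_xlabel(matrix.columns.name or "reference")
    ax.set_ylabel(matrix.index.name or "second site")
    fig.colorbar(im, ax=ax, label="log10 value" if log_scale else "value")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
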