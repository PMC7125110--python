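"""Alignment, per-base mutation frequencies, and rank correlation with
kinetic parameters."""

import numpy as np
import pytest
from scipy import stats

from oracles import brute_force_global_alignment_score, permutation_spearman_p

from glmsarray.alignment import align_pair, make_aligner, normalize_rna
from glmsarray.conservation import (
    correlate_conservation,
    mutation_frequency,
    per_position_symbols,
    single_mutant_frequency,
    spearman_rho_p,
)
from glmsarray.construct import CORE_CONSENSUS
from glmsarray.simulate import KineticEffectModel, simulate_homologs
from glmsarray.variants import RNA_BASES, Variant


def test_identical_sequences_align_gaplessly():
    aln = align_pair(CORE_CONSENSUS, CORE_CONSENSUS)
    assert aln.score == 5.0 * len(CORE_CONSENSUS)
    assert "-" not in str(aln[0]) and "-" not in str(aln[1])


def test_single_deletion_position_is_recoverable():
    query = CORE_CONSENSUS[:29] + CORE_CONSENSUS[30:]  # drop position 30
    aln = align_pair(query, CORE_CONSENSUS)
    symbols = per_position_symbols(aln, len(CORE_CONSENSUS))
    assert symbols.count("-") == 1


@pytest.mark.parametrize(
    "a, b",
    [
        ("ACGUAC", "AGGUAC"),
        ("ACGUAC", "ACUAC"),
        ("GGGAAA", "GGAAAC"),
        ("AUGC", "AUGCGC"),
        ("ACACAC", "CACACA"),
    ],
)
def test_alignment_score_matches_exhaustive_enumeration(a, b):
    aligner = make_aligner()
    assert aligner.score(a, b) == pytest.approx(
        brute_force_global_alignment_score(a, b)
    )


def test_rejects_non_nucleotide_symbols():
    with pytest.raises(ValueError):
        normalize_rna("ACGX")


def test_mutation_frequencies_counted_per_position():
    homologs = [CORE_CONSENSUS] * 3 + [
        CORE_CONSENSUS[:6] + "A" + CORE_CONSENSUS[7:]  # G7A in one of four
    ]
    freq = mutation_frequency(homologs, CORE_CONSENSUS)
    assert freq["f_mut_total"].drop(6).eq(0).all()
    row7 = freq[freq["position"] == 7].iloc[0]
    assert row7["f_A"] == pytest.approx(0.25)
    assert row7["f_mut_total"] == pytest.approx(0.25)
    assert single_mutant_frequency(freq, "G7A") == pytest.approx(0.25)


def test_terminal_truncations_count_as_missing_data():
    homologs = [CORE_CONSENSUS] * 2 + [CORE_CONSENSUS[10:]]  # 5'-truncated
    freq = mutation_frequency(homologs, CORE_CONSENSUS)
    assert (freq.loc[freq["position"] <= 10, "n_seqs"] == 2).all()
    assert (freq.loc[freq["position"] > 10, "n_seqs"] == 3).all()
    assert freq["f_mut_total"].eq(0).all()  # truncation is not a mutation


def test_spearman_extremes_and_scipy_agreement(rng):
    x = np.arange(10.0)
    assert spearman_rho_p(x, x)[0] == pytest.approx(1.0)
    assert spearman_rho_p(x, -x)[0] == pytest.approx(-1.0)
    y = rng.normal(size=30)
    x2 = rng.normal(size=30)
    rho, p = spearman_rho_p(x2, y)
    rho_sp, p_sp = stats.spearmanr(x2, y)
    assert rho == pytest.approx(rho_sp, rel=1e-10)
    assert p == pytest.approx(p_sp, rel=1e-6)
    assert np.isnan(spearman_rho_p(np.ones(5), np.arange(5.0))[0])


def test_p_value_matches_permutation_oracle(rng):
    n = 20
    x = rng.normal(size=n)
    y = 0.6 * x + rng.normal(size=n)
    rho, p = spearman_rho_p(x, y)
    p_perm = permutation_spearman_p(x, y, rho, 10_000, rng)
    assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / 10_000))


def test_synthetic_homologs_link_conservation_to_kcat_not_km(rng):
    """Homologs generated with mutation rates monotone in single-mutant
    k_cat give rho(f_mut, k_cat) significantly > 0, while K_M values drawn
    independently give rho(f_mut, K_M) near 0."""
    model = KineticEffectModel()
    homologs = simulate_homologs(200, seed=11, truncation_prob=0.0)
    freq = mutation_frequency(homologs, CORE_CONSENSUS)
    f_mut, kcat, km = {}, {}, {}
    for pos in range(1, len(CORE_CONSENSUS) + 1):
        ref = CORE_CONSENSUS[pos - 1]
        for alt in sorted(set(RNA_BASES) - {ref}):
            label = f"{ref}{pos}{alt}"
            f_mut[label] = single_mutant_frequency(freq, label)
            kcat[label] = model.k_cat(Variant.from_label(label))
            km[label] = 2.0 * float(np.exp(rng.normal(0, 0.2)))
    res_kcat = correlate_conservation(f_mut, kcat, "k_cat")
    assert res_kcat.rho > 0.4
    assert res_kcat.p_value < 1e-8
    res_km = correlate_conservation(f_mut, km, "K_M")
    assert abs(res_km.rho) < 0.25
    assert res_km.p_value > 0.001
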