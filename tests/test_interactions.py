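"""Double-mutant rescue: the independence expectation, the significance
rule, heatmap construction, and duplex inference."""

import math

import numpy as np
import pytest

from glmsarray.construct import CORE_CONSENSUS, DUPLEXES
from glmsarray.interactions import (
    build_rescue_table,
    compute_rescue,
    expected_independent_rate,
    infer_duplexes,
    rate_matrix,
    rescue_matrix,
)
from glmsarray.simulate import KineticEffectModel
from glmsarray.variants import Mutation, Variant, WATSON_CRICK


def test_independence_expectation_is_product_of_reductions():
    k_c = 0.064
    assert expected_independent_rate(k_c, k_c, k_c) == pytest.approx(k_c)
    assert expected_independent_rate(0.1 * k_c, 0.01 * k_c, k_c) == pytest.approx(
        1e-3 * k_c
    )
    with pytest.raises(ValueError):
        expected_independent_rate(0.0, 1.0, 1.0)


def test_independent_effect_model_obeys_product_rule():
    """With pairing logic disabled, simulated double-mutant rates equal the
    independence expectation exactly; the structure-aware model exceeds it
    for compensatory pairs."""
    indep = KineticEffectModel(independent=True)
    k_c = indep.k_cat_consensus
    i, j = Variant.from_label("G37A"), Variant.from_label("C62U")
    double = Variant.from_label("G37A,C62U")
    assert indep.k_cat(double) == pytest.approx(
        expected_independent_rate(indep.k_cat(i), indep.k_cat(j), k_c), rel=1e-9
    )
    epistatic = KineticEffectModel()
    # the same double restores a Watson-Crick pair in P2: planted epistasis
    assert epistatic.k_cat(double) > expected_independent_rate(
        epistatic.k_cat(i), epistatic.k_cat(j), k_c
    )


def test_rescue_ratio_and_significance_rules():
    ratio, hval, sig, which = compute_rescue(1e-3, 1e-5, 1e-3, 1e-5)
    assert ratio == 1.0 and hval == 1.0 and not sig and which == "single"
    # clear rescue, judged against the single's error
    ratio, hval, sig, which = compute_rescue(6e-3, 1e-4, 1e-4, 1e-5)
    assert ratio == pytest.approx(60.0)
    assert sig and which == "single"
    # single at the floor with undetermined error: fall back to sigma(double)
    ratio, hval, sig, which = compute_rescue(1e-4, 1e-5, 1e-6, math.nan)
    assert which == "double" and sig
    ratio, hval, sig, which = compute_rescue(1e-4, 1e-5, 1e-6, 1e-7)
    assert which == "double"  # floor rule overrides an available sigma
    # sub-background ratios map to the background value 1
    ratio, hval, _, _ = compute_rescue(1e-5, 1e-6, 1e-4, 1e-5)
    assert ratio < 1 and hval == 1.0


def test_rescue_table_is_reciprocal_and_matrix_has_background_one():
    rates = {
        "consensus": (6.4e-2, 1e-3),
        "G7C": (1e-4, 1e-5),
        "G26A": (5e-3, 1e-4),
        "G7C,G26A": (6e-3, 2e-4),
    }
    table = build_rescue_table(rates)
    # the double exceeds both singles: entries appear with both references
    refs = set(table["reference"])
    assert refs == {"G7C", "G26A"}
    row = table[table["reference"] == "G7C"].iloc[0]
    assert row["ratio"] == pytest.approx(60.0)
    assert row["second_site"] == "G26A"
    assert row["fold_vs_consensus"] == pytest.approx(6e-3 / 6.4e-2)
    mat = rescue_matrix(table)
    assert mat.shape == (2, 2)
    assert mat.loc["G26A", "G7C"] == pytest.approx(60.0)
    assert mat.loc["G7C", "G7C"] == 1.0  # background
    rm = rate_matrix(rates)
    assert rm.loc["G7C", "G7C"] == pytest.approx(1e-4)  # singles on diagonal
    assert rm.loc["G7C", "G26A"] == pytest.approx(6e-3)


def test_no_rescues_gives_all_background_matrix():
    rates = {
        "consensus": (6.4e-2, 1e-3),
        "G7C": (1e-4, 1e-5),
        "G26A": (5e-3, 1e-4),
        "G7C,G26A": (1e-5, 1e-6),  # double worse than both singles
    }
    mat = rescue_matrix(build_rescue_table(rates))
    assert (mat.to_numpy() == 1.0).all()


def _planted_rates(noise_frac: float, seed: int = 0) -> dict:
    """Rates for all duplex singles and all WC-restoring doubles (plus
    mismatch decoys) where the rate is determined solely by the
    Watson-Crick pairing status of the designed duplex positions, with
    multiplicative lognormal noise."""
    model = KineticEffectModel(catalytic_positions=frozenset())
    rng = np.random.default_rng(seed)
    variants = {"consensus"}
    for pairs in DUPLEXES.values():
        for p, q in pairs:
            bp, bq = CORE_CONSENSUS[p - 1], CORE_CONSENSUS[q - 1]
            for x in sorted(set("ACGU") - {bp}):
                variants.add(f"{bp}{p}{x}")
                y = WATSON_CRICK[x]
                if y != bq:
                    variants.add(f"{bq}{q}{y}")
                variants.add(f"{bp}{p}{x},{bq}{q}{y}")  # restoring double
                z = sorted(set("ACGU") - {bq, y})[0]  # mismatch decoy
                variants.add(f"{bp}{p}{x},{bq}{q}{z}")
    rates = {}
    for label in sorted(variants):
        v = Variant.from_label(label)
        k = model.k_cat(v) * float(np.exp(rng.normal(0, noise_frac)))
        rates[label] = (k, noise_frac * k if label != "consensus" else 1e-3)
    return rates


def test_planted_duplexes_recovered_with_no_false_calls():
    """Every designed duplex shows up as an anti-diagonal run of rescues and
    nothing else does (effect size >= 10x, 10% noise)."""
    rates = _planted_rates(noise_frac=0.10)
    table = build_rescue_table(rates)
    calls = infer_duplexes(table, CORE_CONSENSUS)
    called_pairs = {pq for duplex in calls for pq in duplex}
    planted = {pq for pairs in DUPLEXES.values() for pq in pairs}
    assert called_pairs <= planted, f"false duplex calls: {called_pairs - planted}"
    # every planted pair except the bulge-isolated 7-52 (which cannot form a
    # 3-pair anti-diagonal run) is recovered, so all four duplex elements show
    assert called_pairs == planted - {(7, 52)}
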