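"""Barcode consensus calling and cluster-to-variant assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import exact_binomial_tail

from glmsarray.barcodes import (
    ASSIGNED,
    UNASSIGNED,
    UNKNOWN_BARCODE,
    assign_clusters,
    assign_variant,
    binomial_tail_p,
    build_consensus_map,
    call_consensus,
)
from glmsarray.construct import FULL_CONSTRUCT
from glmsarray.simulate import (
    LibraryDesign,
    build_ground_truth,
    default_schedule,
    clusters_to_frame,
    simulate_clusters,
    simulate_library,
    simulate_reads,
)


def test_unanimous_reads_are_kept():
    group = call_consensus(["ACGU"] * 10)
    assert group.kept
    assert group.consensus == "ACGU"
    assert np.allclose(group.p_values, 0.25**10)
    assert np.all(group.match_fractions == 1.0)


def test_seven_of_ten_majority_passes_both_filters():
    """70% majority passes the 66% rule and the binomial test
    (P(X>=7 | n=10, p=0.25) ~ 0.0035 < 0.05)."""
    reads = ["AAAA"] * 7 + ["CCCC"] * 3
    group = call_consensus(reads)
    assert group.kept
    assert group.consensus == "AAAA"
    assert group.match_fractions[0] == pytest.approx(0.7)
    assert group.p_values[0] == pytest.approx(exact_binomial_tail(7, 10), rel=1e-12)
    assert group.p_values[0] == pytest.approx(0.0035, abs=5e-4)


def test_three_way_tie_fails_majority_rule():
    group = call_consensus(["AAAA", "CAAA", "GAAA"])
    assert not group.kept
    assert group.consensus is None
    assert group.match_fractions[0] == pytest.approx(1 / 3)


def test_deviant_length_reads_count_against_match_fraction():
    # 6 full-length identical reads, 4 shorter ones: fraction 0.6 < 0.66
    reads = ["ACGUACGU"] * 6 + ["ACGU"] * 4
    group = call_consensus(reads)
    assert len(group.modal_sequence) == 8
    assert group.match_fractions[0] == pytest.approx(0.6)
    assert not group.kept


@pytest.mark.parametrize("n", [1, 2, 5, 8, 12])
def test_binomial_p_matches_exact_enumeration(n):
    for count in range(n + 1):
        assert binomial_tail_p(count, n) == pytest.approx(
            exact_binomial_tail(count, n), rel=1e-10, abs=1e-300
        )


@settings(derandomize=True, max_examples=40)
@given(
    st.lists(
        st.text(alphabet="ACGU", min_size=4, max_size=4), min_size=2, max_size=12
    )
)
def test_raising_match_threshold_never_keeps_more(reads):
    """Keep decisions are monotone in the match-fraction threshold."""
    loose = call_consensus(reads, min_match_fraction=0.66)
    strict = call_consensus(reads, min_match_fraction=0.8)
    assert not (strict.kept and not loose.kept)


def test_hamming_threshold_boundary():
    group = call_consensus(["AAAAAAAA"] * 10)
    cmap = {"BC1": group}
    two_off = "AACCAAAA"
    three_off = "AACCCAAA"
    assert assign_variant(two_off, "BC1", cmap)[0] == ASSIGNED
    assert assign_variant(three_off, "BC1", cmap)[0] == UNASSIGNED
    assert assign_variant(two_off, "missing", cmap)[0] == UNKNOWN_BARCODE
    # length-changing reads cannot pass an equal-length Hamming comparison
    assert assign_variant("AAAA", "BC1", cmap)[0] == UNASSIGNED


def test_error_free_reads_assign_every_cluster_to_its_variant():
    """End-to-end against simulator ground truth with zero sequencing error:
    every barcode consensus equals the generating sequence and every cluster
    is assigned to its generating variant."""
    design = LibraryDesign(bottleneck_size=120)
    lib = simulate_library(design, 5)
    truth = build_ground_truth(
        [v for v, _ in lib], default_schedule(), 0, n_tiles=2
    )
    clusters = simulate_clusters(lib, truth, 10.0, 2, seed=6, design=design)
    reads = simulate_reads(clusters, n_reads=3, error_rate=0.0, seed=7)
    groups, summary = build_consensus_map(reads)
    assert summary["kept"].all()
    by_barcode = {c.barcode: c.true_sequence for c in clusters}
    for barcode, group in groups.items():
        assert group.consensus == by_barcode[barcode]
    assigned = assign_clusters(
        clusters_to_frame(clusters), groups, design.consensus_sequence, design.flank
    )
    assert (assigned["assignment_status"] == ASSIGNED).all()
    assert (assigned["variant"] == assigned["true_variant"]).all()


def test_empty_read_set_rejected():
    with pytest.raises(ValueError):
        call_consensus([])
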