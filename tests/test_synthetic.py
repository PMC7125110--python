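"""Simulator statistics: doping process, bottleneck, trace forward model."""

import numpy as np
import pytest
from scipy import stats

from glmsarray.construct import FULL_CONSTRUCT
from glmsarray.simulate import (
    CONSENSUS_K_CAT,
    ImagingSchedule,
    LibraryDesign,
    GroundTruth,
    build_ground_truth,
    default_schedule,
    optimal_two_mismatch_doping,
    simulate_clusters,
    simulate_library,
)
from glmsarray.variants import Variant


def _design(**kw):
    defaults = dict(bottleneck_size=1000)
    defaults.update(kw)
    return LibraryDesign(**defaults)


def test_no_mutation_limit_yields_only_consensus():
    design = _design(
        doping_fraction=0.0, deletion_rate=0.0, double_incorporation_rate=0.0
    )
    lib = simulate_library(design, 0)
    assert lib == [(Variant(), design.bottleneck_size)]


def test_substitution_counts_match_binomial():
    """At 1.3% per non-consensus base over 54 doped positions, per-molecule
    substitution counts follow Binomial(54, 0.039) within Monte-Carlo error."""
    n = 100_000
    design = _design(
        doping_fraction=0.013,
        deletion_rate=0.0,
        double_incorporation_rate=0.0,
        bottleneck_size=n,
    )
    assert len(design.doped_indices()) == 54
    lib = simulate_library(design, 7)
    counts = np.zeros(55)
    for v, a in lib:
        counts[v.n_mutations] += a
    empirical = counts / n
    pmf = stats.binom.pmf(np.arange(55), 54, 3 * 0.013)
    for k in range(6):
        tol = 4 * np.sqrt(pmf[k] * (1 - pmf[k]) / n) + 1e-4
        assert abs(empirical[k] - pmf[k]) < tol, (k, empirical[k], pmf[k])


def test_doping_rate_maximising_double_mutants():
    """Grid search over the doping rate confirms the closed-form optimum of
    ~0.0123 per non-consensus base for maximising two-mismatch molecules."""
    grid = np.linspace(1e-4, 0.05, 20_000)
    frac2 = [
        stats.binom.pmf(2, 54, 3 * d) for d in grid
    ]
    d_star = grid[int(np.argmax(frac2))]
    assert abs(d_star - 0.0123) < 5e-4
    assert abs(optimal_two_mismatch_doping(54) - d_star) < 5e-4


def test_event_probabilities_must_not_exceed_one():
    with pytest.raises(ValueError):
        _design(doping_fraction=0.3, deletion_rate=0.2)


def test_library_reproducible_and_barcodes_distinct():
    design = _design(bottleneck_size=500)
    assert simulate_library(design, 3) == simulate_library(design, 3)
    lib = simulate_library(design, 3)
    truth = build_ground_truth([v for v, _ in lib], default_schedule(), 0, n_tiles=2)
    cl_a = simulate_clusters(lib, truth, 10.0, 2, seed=1, design=design)
    cl_b = simulate_clusters(lib, truth, 10.0, 2, seed=2, design=design)
    bc_a = [c.barcode for c in cl_a]
    bc_b = [c.barcode for c in cl_b]
    assert set(bc_a) != set(bc_b)
    # collisions within a run stay near the birthday bound for 4^16 space
    assert len(set(bc_a)) == len(bc_a)


@pytest.fixture()
def flat_truth():
    schedule = ImagingSchedule((0.0, 0.0, 36.0, 100.0, 1000.0, 10_000.0))
    consensus = Variant()
    return GroundTruth(
        kinetics={consensus: (CONSENSUS_K_CAT, 2.0)},
        tile_gains={0: np.ones(6)},
        noise_sd=0.0,
        schedule=schedule,
    )


def test_trace_matches_closed_form_decay(flat_truth):
    """With k_obs = 6.4e-2 1/s and flat gain, the trace at t = 36 s equals
    baseline * exp(-2.304) ~ 0.0999 * baseline."""
    lib = [(Variant(), 1)]
    (cl,) = simulate_clusters(
        lib, flat_truth, 10.0, 1, seed=0, baseline_cv=0.0
    )
    baseline = cl.intensities[0]
    assert cl.intensities[1] == pytest.approx(baseline)
    assert cl.intensities[2] / baseline == pytest.approx(
        np.exp(-6.4e-2 * 36.0), rel=1e-12
    )
    assert cl.intensities[2] / baseline == pytest.approx(0.0999, abs=1e-4)


def test_no_ligand_and_dead_variant_limits(flat_truth):
    lib = [(Variant(), 1)]
    (cl,) = simulate_clusters(lib, flat_truth, 0.0, 1, seed=0, baseline_cv=0.0)
    assert np.allclose(cl.intensities, cl.intensities[0])  # C = 0 -> k_obs = 0
    dead = GroundTruth(
        kinetics={Variant(): (0.0, 2.0)},
        tile_gains=flat_truth.tile_gains,
        noise_sd=0.0,
        schedule=flat_truth.schedule,
    )
    (cl0,) = simulate_clusters(lib, dead, 10.0, 1, seed=0, baseline_cv=0.0)
    assert np.allclose(cl0.intensities, cl0.intensities[0])


def test_noiseless_log_trace_is_linear(schedule):
    lib = [(Variant(), 1)]
    truth = build_ground_truth(
        [Variant()], schedule, 0, n_tiles=1, noise_sd=0.0, flat_gain=True
    )
    (cl,) = simulate_clusters(lib, truth, 10.0, 1, seed=0, baseline_cv=0.0)
    t = schedule.t_post
    mask = cl.intensities > 0  # fast decay underflows at the latest times
    logs = np.log(cl.intensities[mask] / cl.intensities[0])
    k_obs = truth.k_obs(Variant(), 10.0)
    assert np.allclose(logs, -k_obs * t[mask], atol=1e-9)
    assert mask[:20].all()


def test_cluster_simulation_rejects_bad_inputs(flat_truth):
    with pytest.raises(ValueError):
        simulate_clusters([], flat_truth, 10.0, 1, seed=0)
    with pytest.raises(ValueError):
        simulate_clusters([(Variant(), 1)], flat_truth, -1.0, 1, seed=0)


def test_schedule_requires_baseline_pair():
    with pytest.raises(ValueError):
        ImagingSchedule((0.0, 10.0, 20.0, 30.0))
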