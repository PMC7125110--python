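"""Exponential decay fitting, BIC selection, rate extraction, and the gel
fraction-cleaved model."""

import math

import numpy as np
import pytest

from oracles import grid_search_single_exp

from glmsarray.kinetics import (
    DecayModel,
    ExpFit,
    FitBounds,
    bic,
    extract_rate,
    fit_double_exp,
    fit_fraction_cleaved,
    fit_single_exp,
    fraction_cleaved,
    select_model_bic,
)


def test_exact_single_exponential_is_recovered(t_post):
    y = np.exp(-0.01 * t_post)
    fit = fit_single_exp(t_post, y)
    assert fit.params["k"] == pytest.approx(0.01, rel=1e-3)
    assert fit.params["a"] == pytest.approx(1.0, rel=1e-3)
    assert fit.params["b"] == pytest.approx(0.0, abs=1e-3)


def test_constant_series_lands_at_rate_floor(t_post):
    fit = DecayModel(t_post, np.ones_like(t_post)).fit()
    assert fit.model == "single"
    assert fit.below_floor
    assert fit.k_obs <= 1e-6


def test_single_fit_matches_grid_search_oracle(t_post, rng):
    """The LM fit agrees with a dense brute-force grid minimizer within 1%
    on seeded noisy instances."""
    for k_true in (3e-4, 5e-3, 4e-2):
        y = np.exp(-k_true * t_post) + rng.normal(0, 0.01, len(t_post))
        fit = fit_single_exp(t_post, y)
        k_grid, *_ = grid_search_single_exp(t_post, y, k_true / 30, k_true * 30)
        assert fit.params["k"] == pytest.approx(k_grid, rel=0.01)


def test_double_exponential_parameter_recovery(t_post, rng):
    y = 0.5 * np.exp(-0.1 * t_post) + 0.5 * np.exp(-0.001 * t_post)
    y = y + rng.normal(0, 0.01, len(t_post))
    fit = fit_double_exp(t_post, y)
    assert fit.params["k_fast"] == pytest.approx(0.1, rel=0.05)
    assert fit.params["k_slow"] == pytest.approx(0.001, rel=0.05)
    assert fit.params["f_fast"] == pytest.approx(0.5, abs=0.05)
    assert fit.params["k_fast"] >= fit.params["k_slow"]


@pytest.mark.parametrize("f_true", [1.0, 0.0])
def test_double_model_nests_single(t_post, f_true):
    """With all amplitude in one phase, the double fit's extracted rate
    matches the single-exponential fit on the same data."""
    k_true = 0.005
    y = np.exp(-k_true * t_post)
    single = fit_single_exp(t_post, y)
    double = fit_double_exp(t_post, y, init_from=single)
    k, _sigma, _f = extract_rate(double)
    assert k == pytest.approx(single.params["k"], rel=0.02)


def test_bic_selection_operating_characteristics(t_post):
    """On truly single-exponential data the dBIC >= 10 rule rarely picks the
    double model; strongly biphasic data always selects it."""
    rng = np.random.default_rng(42)
    n_double = 0
    reps = 200
    for _ in range(reps):
        y = np.exp(-0.005 * t_post) + rng.normal(0, 0.02, len(t_post))
        single = fit_single_exp(t_post, y)
        double = fit_double_exp(t_post, y, init_from=single)
        if select_model_bic(single, double) == "double":
            n_double += 1
    assert n_double / reps < 0.05

    y_bi = 0.5 * np.exp(-0.05 * t_post) + 0.5 * np.exp(-5e-4 * t_post)
    n_double_bi = 0
    for _ in range(50):
        y = y_bi + rng.normal(0, 0.005, len(t_post))
        single = fit_single_exp(t_post, y)
        double = fit_double_exp(t_post, y, init_from=single)
        # cross-check the criterion against independently computed BICs
        assert single.bic == pytest.approx(
            bic(single.rss, len(t_post), 3), rel=1e-12
        )
        if single.bic - double.bic >= 10:
            assert select_model_bic(single, double) == "double"
            n_double_bi += 1
    assert n_double_bi / 50 > 0.95


@pytest.mark.parametrize(
    "f_fast, expect", [(0.5, "k_fast"), (0.05, "k_slow"), (0.10, "k_fast")]
)
def test_fast_rate_amplitude_rule(f_fast, expect):
    """The faster rate represents the cleavage rate only when it carries at
    least 10% of the decay amplitude (boundary inclusive)."""
    fit = ExpFit(
        model="double",
        params={"a": 1.0, "f_fast": f_fast, "k_fast": 0.1, "k_slow": 0.001, "b": 0.0},
        stderr={"k_fast": 0.01, "k_slow": 0.0001},
        rss=1e-4,
        n=50,
        success=True,
    )
    k, sigma, _ = extract_rate(fit, amplitude_min=0.10)
    assert k == fit.params[expect]
    assert sigma == fit.stderr[expect]


def test_pure_noise_series_fails_quality_filter(t_post, rng):
    y = rng.uniform(0, 1, len(t_post))
    fit = DecayModel(t_post, y).fit(max_bic=-200.0)
    assert not fit.quality_pass


def test_minimum_point_requirements():
    with pytest.raises(ValueError):
        fit_single_exp([0, 1, 2], [1, 1, 1])
    with pytest.raises(ValueError):
        fit_double_exp([0, 1, 2, 3, 4], [1, 1, 1, 1, 1])


def test_fraction_cleaved_limits_and_recovery(rng):
    t = np.array(
        [0.0, 5, 10, 20, 30, 45, 60, 90, 120, 180, 300, 450, 600, 900,
         1200, 1800, 2400, 3600, 4800, 7200, 9600, 12000]
    )
    params = dict(F0=0.05, Fmax=0.9, f_fast=0.7, k_fast=0.05, k_slow=0.002)
    assert fraction_cleaved(np.array([0.0]), **params)[0] == pytest.approx(0.05)
    assert fraction_cleaved(np.array([1e9]), **params)[0] == pytest.approx(0.9)
    F = fraction_cleaved(t, **params) + rng.normal(0, 0.0015, len(t))
    gel = fit_fraction_cleaved(t, np.clip(F, 0, 1))
    assert gel.success
    assert gel.F0 == pytest.approx(0.05, abs=0.02)
    assert gel.Fmax == pytest.approx(0.9, rel=0.05)
    assert gel.f_fast == pytest.approx(0.7, abs=0.05)
    assert gel.k_fast == pytest.approx(0.05, rel=0.05)
    assert gel.k_slow == pytest.approx(0.002, rel=0.05)
    assert gel.k_fast >= gel.k_slow >= 0
    assert 0 <= gel.F0 <= gel.Fmax <= 1
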