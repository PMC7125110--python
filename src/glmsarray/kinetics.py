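"""Exponential decay fitting with BIC model selection.

A normalized per-variant decay series is fit to two nested models of the
surviving (uncleaved) signal fraction:

    single:  y(t) = a * exp(-k t) + b
    double:  y(t) = a * [f exp(-k_fast t) + (1 - f) exp(-k_slow t)] + b

by Levenberg-Marquardt least squares (lmfit) with box constraints on every
parameter.  The additive offset ``b`` absorbs an incompletely cleaved or
non-releasing signal fraction.  The single exponential is adopted unless the
double fit improves the Bayesian Information Criterion,

    BIC = n ln(RSS / n) + p ln(n),

by at least 10 units ("very strong" evidence).  The characteristic cleavage
rate k_obs is the faster rate of the chosen model provided it carries at
least 10% of the decay amplitude, otherwise the slower rate.

The module also provides the gel-based fraction-cleaved model

    F(t) = F(0) + [Fmax - F(0)] {1 - [f_fast exp(-k_fast t)
                                      + (1 - f_fast) exp(-k_slow t)]}

used for bulk-solution cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

MODEL_SINGLE = "single"
MODEL_DOUBLE = "double"


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the decay fits (units: 1/s for rates)."""

    k_min: float = 1e-7
    k_max: float = 1.0
    a_max: float = 2.0
    b_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.k_min < self.k_max:
            raise ValueError("need 0 < k_min < k_max")
        if self.a_max <= 0 or self.b_max < 0:
            raise ValueError("bad amplitude/offset bounds")


DEFAULT_BOUNDS = FitBounds()


def bic(rss: float, n: int, n_params: int) -> float:
    """Gaussian-residual BIC: n ln(RSS/n) + p ln(n)."""
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + n_params * math.log(n)


@dataclass
class ExpFit:
    """One converged exponential fit (single or double)."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    n: int
    success: bool

    @property
    def n_params(self) -> int:
        return 3 if self.model == MODEL_SINGLE else 5

    @property
    def bic(self) -> float:
        return bic(self.rss, self.n, self.n_params)


def _single_model(t: np.ndarray, a: float, k: float, b: float) -> np.ndarray:
    return a * np.exp(-k * t) + b


def _double_model(
    t: np.ndarray, a: float, f: float, k_fast: float, k_slow: float, b: float
) -> np.ndarray:
    return a * (f * np.exp(-k_fast * t) + (1 - f) * np.exp(-k_slow * t)) + b


def _initial_guesses(t: np.ndarray, y: np.ndarray, bounds: FitBounds) -> tuple:
    b0 = float(np.clip(np.median(y[-3:]), 0.0, bounds.b_max))
    a0 = float(np.clip(y[0] - b0, 1e-3, bounds.a_max))
    threshold = b0 + a0 / math.e
    below = np.nonzero(y < threshold)[0]
    if len(below) and t[below[0]] > 0:
        k0 = 1.0 / t[below[0]]
    else:
        k0 = bounds.k_min * 10
    k0 = float(np.clip(k0, bounds.k_min, bounds.k_max))
    return a0, k0, b0


def fit_single_exp(
    t: Sequence[float],
    y: Sequence[float],
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> ExpFit:
    """Constrained least-squares fit of a single exponential with offset.

    A small multistart over the rate (decade around the half-decay guess)
    guards against local minima; the best residual sum of squares wins, with
    ties going to the slowest rate.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 4:
        raise ValueError("single-exponential fit needs >= 4 points")
    a0, k0, b0 = _initial_guesses(t, y, bounds)
    best = None
    for k_start in sorted(
        {
            float(np.clip(k0 * s, bounds.k_min, bounds.k_max))
            for s in (0.1, 1.0, 10.0)
        }
    ):
        p = lmfit.Parameters()
        p.add("a", value=a0, min=0.0, max=bounds.a_max)
        p.add("k", value=k_start, min=bounds.k_min, max=bounds.k_max)
        p.add("b", value=b0, min=0.0, max=bounds.b_max)
        try:
            res = lmfit.minimize(
                lambda pars: _single_model(t, pars["a"], pars["k"], pars["b"]) - y,
                p,
                method="leastsq",
            )
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0] * (1 - 1e-12):
            best = (rss, res)
    if best is None:
        return ExpFit(MODEL_SINGLE, {}, {}, math.inf, len(t), False)
    rss, res = best
    params = {name: float(res.params[name].value) for name in ("a", "k", "b")}
    stderr = {
        name: float(res.params[name].stderr)
        if res.params[name].stderr is not None
        else math.nan
        for name in ("a", "k", "b")
    }
    return ExpFit(MODEL_SINGLE, params, stderr, rss, len(t), True)


def fit_double_exp(
    t: Sequence[float],
    y: Sequence[float],
    bounds: FitBounds = DEFAULT_BOUNDS,
    init_from: ExpFit | None = None,
) -> ExpFit:
    """Constrained fit of the two-rate model.

    The two rates are fit symmetrically and relabelled afterwards so that
    k_fast >= k_slow (swapping f for 1 - f), which keeps each rate's
    covariance-derived error attached to the right parameter.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 6:
        raise ValueError("double-exponential fit needs >= 6 points")
    if init_from is not None and init_from.success:
        a0 = init_from.params["a"]
        k0 = init_from.params["k"]
        b0 = init_from.params["b"]
    else:
        a0, k0, b0 = _initial_guesses(t, y, bounds)
    k1 = float(np.clip(k0 * 5, bounds.k_min, bounds.k_max))
    k2 = float(np.clip(k0 / 5, bounds.k_min, bounds.k_max))
    p = lmfit.Parameters()
    p.add("a", value=max(a0, 1e-3), min=0.0, max=bounds.a_max)
    p.add("f", value=0.5, min=0.0, max=1.0)
    p.add("k1", value=k1, min=bounds.k_min, max=bounds.k_max)
    p.add("k2", value=k2, min=bounds.k_min, max=bounds.k_max)
    p.add("b", value=b0, min=0.0, max=bounds.b_max)
    try:
        res = lmfit.minimize(
            lambda pars: _double_model(
                t, pars["a"], pars["f"], pars["k1"], pars["k2"], pars["b"]
            )
            - y,
            p,
            method="leastsq",
        )
    except Exception:
        return ExpFit(MODEL_DOUBLE, {}, {}, math.inf, len(t), False)
    rss = float(np.sum(res.residual**2))

    def val(name):
        return float(res.params[name].value)

    def err(name):
        e = res.params[name].stderr
        return float(e) if e is not None else math.nan

    if val("k1") >= val("k2"):
        fast, slow, f_fast = "k1", "k2", val("f")
        f_err = err("f")
    else:
        fast, slow, f_fast = "k2", "k1", 1.0 - val("f")
        f_err = err("f")
    params = {
        "a": val("a"),
        "f_fast": f_fast,
        "k_fast": val(fast),
        "k_slow": val(slow),
        "b": val("b"),
    }
    stderr = {
        "a": err("a"),
        "f_fast": f_err,
        "k_fast": err(fast),
        "k_slow": err(slow),
        "b": err("b"),
    }
    return ExpFit(MODEL_DOUBLE, params, stderr, rss, len(t), True)


def select_model_bic(
    fit_single: ExpFit, fit_double: ExpFit, delta: float = 10.0
) -> str:
    """Adopt the single exponential unless the double fit improves the BIC
    by at least ``delta`` units; a failed fit forfeits."""
    if not fit_single.success:
        return MODEL_DOUBLE if fit_double.success else MODEL_SINGLE
    if not fit_double.success:
        return MODEL_SINGLE
    return (
        MODEL_DOUBLE
        if fit_single.bic - fit_double.bic >= delta
        else MODEL_SINGLE
    )


def extract_rate(
    fit: ExpFit, amplitude_min: float = 0.10
) -> tuple[float, float, float]:
    """Characteristic cleavage rate from the chosen fit.

    Single model: its rate.  Double model: the faster rate provided it
    carries at least ``amplitude_min`` of the decay amplitude, otherwise the
    slower rate.  Returns (k_obs, sigma_k_obs, f_fast); f_fast is NaN for
    the single model.
    """
    if fit.model == MODEL_SINGLE:
        return fit.params["k"], fit.stderr["k"], math.nan
    f_fast = fit.params["f_fast"]
    which = "k_fast" if f_fast >= amplitude_min else "k_slow"
    return fit.params[which], fit.stderr[which], f_fast


@dataclass
class DecayFit:
    """Results of fitting one normalized decay series.

    Carries the chosen model, the characteristic rate with its
    covariance-derived error, both information criteria, and quality flags.
    """

    model: str
    k_obs: float
    sigma_k_obs: float
    amplitude_fraction_fast: float
    bic_single: float
    bic_double: float
    quality_pass: bool
    below_floor: bool
    n_points: int
    single: ExpFit
    double: ExpFit | None

    @property
    def chosen(self) -> ExpFit:
        return self.single if self.model == MODEL_SINGLE else self.double

    def summary(self) -> str:
        lines = [
            "Exponential decay fit",
            "=" * 42,
            f"points                {self.n_points}",
            f"model                 {self.model}",
            f"k_obs (1/s)           {self.k_obs:.4g}",
            f"sigma k_obs (1/s)     {self.sigma_k_obs:.4g}",
            f"BIC single / double   {self.bic_single:.1f} / {self.bic_double:.1f}",
            f"quality pass          {self.quality_pass}",
            f"below detection floor {self.below_floor}",
        ]
        if self.model == MODEL_DOUBLE:
            lines.insert(5, f"fast amplitude f      {self.amplitude_fraction_fast:.3f}")
        return "\n".join(lines)


class DecayModel:
    """Normalized decay series ready to fit (statsmodels-style model object).

    Parameters
    ----------
    t_post : seconds since ligand introduction for each observation.
    values : normalized intensities (dimensionless).
    bounds : box constraints on rates/amplitudes.
    """

    def __init__(
        self,
        t_post: Sequence[float],
        values: Sequence[float],
        bounds: FitBounds = DEFAULT_BOUNDS,
    ) -> None:
        self.t = np.asarray(t_post, float)
        self.y = np.asarray(values, float)
        if self.t.shape != self.y.shape:
            raise ValueError("t_post and values must have equal length")
        self.bounds = bounds

    @classmethod
    def from_series(
        cls, series, bounds: FitBounds = DEFAULT_BOUNDS
    ) -> "DecayModel":
        """Build from a long-format normalized series table
        (columns t_post_s, value); rows from several tiles concatenate as
        independent observations."""
        return cls(series["t_post_s"].to_numpy(), series["value"].to_numpy(), bounds)

    def fit(
        self,
        delta_bic: float = 10.0,
        amplitude_min: float = 0.10,
        rate_floor: float = 1e-6,
        max_bic: float | None = None,
    ) -> DecayFit:
        single = fit_single_exp(self.t, self.y, self.bounds)
        double = None
        if len(self.t) >= 6:
            double = fit_double_exp(self.t, self.y, self.bounds, init_from=single)
        if double is None:
            double = ExpFit(MODEL_DOUBLE, {}, {}, math.inf, len(self.t), False)
        model = select_model_bic(single, double, delta_bic)
        chosen = single if model == MODEL_SINGLE else double
        k, sigma, f_fast = extract_rate(chosen, amplitude_min)
        chosen_bic = chosen.bic if chosen.success else math.inf
        quality = chosen.success and (max_bic is None or chosen_bic <= max_bic)
        return DecayFit(
            model=model,
            k_obs=k,
            sigma_k_obs=sigma,
            amplitude_fraction_fast=f_fast,
            bic_single=single.bic if single.success else math.inf,
            bic_double=double.bic if double.success else math.inf,
            quality_pass=quality,
            below_floor=k <= rate_floor,
            n_points=len(self.t),
            single=single,
            double=double if double.success else None,
        )


# ---------------------------------------------------------------------------
# gel-based fraction cleaved (bulk-solution cross-check)
# ---------------------------------------------------------------------------


@dataclass
class GelFit:
    """Parameters of the fraction-cleaved double-exponential model."""

    F0: float
    Fmax: float
    f_fast: float
    k_fast: float
    k_slow: float
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = math.nan
    success: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        return fraction_cleaved(
            np.asarray(t, float), self.F0, self.Fmax, self.f_fast,
            self.k_fast, self.k_slow,
        )


def fraction_cleaved(
    t: np.ndarray, F0: float, Fmax: float, f_fast: float,
    k_fast: float, k_slow: float,
) -> np.ndarray:
    """F(t) = F0 + (Fmax - F0) {1 - [f exp(-k_fast t) + (1-f) exp(-k_slow t)]}."""
    decay = f_fast * np.exp(-k_fast * t) + (1 - f_fast) * np.exp(-k_slow * t)
    return F0 + (Fmax - F0) * (1 - decay)


def fit_fraction_cleaved(
    times: Sequence[float],
    fractions: Sequence[float],
    k_min: float = 1e-7,
    k_max: float = 10.0,
) -> GelFit:
    """Least-squares fit of the gel fraction-cleaved model.

    Enforces 0 <= F0 <= Fmax <= 1 (via a nonnegative span parameter) and
    k_fast >= k_slow by relabelling.
    """
    t = np.asarray(times, float)
    F = np.asarray(fractions, float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if len(t) < 6:
        raise ValueError("gel fit needs >= 6 points")
    p = lmfit.Parameters()
    p.add("F0", value=float(np.clip(F[np.argmin(t)], 0, 1)), min=0.0, max=1.0)
    p.add("span", value=float(np.clip(F.max() - F.min(), 0.05, 1.0)), min=0.0, max=1.0)
    p.add("Fmax", expr="min(F0 + span, 1)")
    p.add("f", value=0.5, min=0.0, max=1.0)
    t_half = max(t[t > 0].min(), 1.0)
    p.add("k1", value=min(1.0 / t_half, k_max), min=k_min, max=k_max)
    p.add("k2", value=min(0.01 / t_half, k_max), min=k_min, max=k_max)

    def resid(pars):
        return (
            fraction_cleaved(
                t, pars["F0"], pars["Fmax"], pars["f"], pars["k1"], pars["k2"]
            )
            - F
        )

    try:
        res = lmfit.minimize(resid, p, method="leastsq")
    except Exception:
        return GelFit(math.nan, math.nan, math.nan, math.nan, math.nan, {}, math.nan, False)

    def val(n):
        return float(res.params[n].value)

    def err(n):
        e = res.params[n].stderr
        return float(e) if e is not None else math.nan

    if val("k1") >= val("k2"):
        kf, ks, f = val("k1"), val("k2"), val("f")
        ef, es = err("k1"), err("k2")
    else:
        kf, ks, f = val("k2"), val("k1"), 1.0 - val("f")
        ef, es = err("k2"), err("k1")
    stderr = {"F0": err("F0"), "Fmax": err("Fmax"), "f_fast": err("f"),
              "k_fast": ef, "k_slow": es}
    return GelFit(
        F0=val("F0"), Fmax=val("Fmax"), f_fast=f, k_fast=kf, k_slow=ks,
        stderr=stderr, rss=float(np.sum(res.residual**2)), success=True,
    )
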