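"""Weighted Michaelis-Menten fits across ligand concentrations.

For each variant, the per-concentration observed cleavage rates k_obs(C)
with their covariance-derived errors sigma(k_obs) are fit to

    k_obs(C) = k_cat * C / (K_M + C)

by inverse-variance weighted least squares (chi-square), minimising
sum[((k_obs - model) / sigma)^2].  Parameter errors come from the fit
covariance without reduced-chi-square rescaling, since the weights are real
measurement errors.  Following the acceptance rule used downstream, a
parameter is accepted only when its error is smaller than its value:
sigma(k_cat) < k_cat and sigma(K_M) < K_M, judged independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import lmfit
import numpy as np


def mm_rate(
    concentration_mm: np.ndarray | float, k_cat: float, K_M: float
) -> np.ndarray | float:
    """Michaelis-Menten forward model k_obs(C) = k_cat C / (K_M + C)."""
    return k_cat * concentration_mm / (K_M + concentration_mm)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-concentration rates for one variant (concentrations in mM,
    strictly increasing; rates in 1/s)."""

    concentrations: tuple[float, ...]
    k_obs: tuple[float, ...]
    sigma_k_obs: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        if len(c) != len(self.k_obs) or len(c) != len(self.sigma_k_obs):
            raise ValueError("length mismatch")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive, strictly increasing")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class MMFit:
    """Michaelis-Menten results: estimates, errors, efficiency, acceptance."""

    k_cat: float
    K_M: float
    sigma_k_cat: float
    sigma_K_M: float
    n_points: int
    chisqr: float
    success: bool
    accepted_kcat: bool = False
    accepted_KM: bool = False

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency k_cat / K_M (1/s/mM)."""
        return self.k_cat / self.K_M

    def summary(self) -> str:
        return "\n".join(
            [
                "Michaelis-Menten fit",
                "=" * 42,
                f"points                {self.n_points}",
                f"k_cat (1/s)           {self.k_cat:.4g} +/- {self.sigma_k_cat:.2g}"
                f"   accepted: {self.accepted_kcat}",
                f"K_M (mM)              {self.K_M:.4g} +/- {self.sigma_K_M:.2g}"
                f"   accepted: {self.accepted_KM}",
                f"k_cat/K_M (1/s/mM)    {self.efficiency:.4g}",
                f"chi-square            {self.chisqr:.4g}",
            ]
        )


def filter_kinetic_params(fit: MMFit) -> MMFit:
    """Apply the sigma-based acceptance rule, independently per parameter."""
    return replace(
        fit,
        accepted_kcat=bool(
            fit.success
            and math.isfinite(fit.sigma_k_cat)
            and fit.sigma_k_cat < fit.k_cat
        ),
        accepted_KM=bool(
            fit.success
            and math.isfinite(fit.sigma_K_M)
            and fit.sigma_K_M < fit.K_M
        ),
    )


class MichaelisMentenModel:
    """Weighted MM model for one variant's concentration series."""

    def __init__(self, series: ConcentrationSeries, km_bounds=(1e-3, 1e3)) -> None:
        if len(series) < 3:
            raise ValueError("Michaelis-Menten fit needs >= 3 concentrations")
        self.series = series
        self.km_bounds = km_bounds

    def fit(self) -> MMFit:
        c = np.asarray(self.series.concentrations, float)
        k = np.asarray(self.series.k_obs, float)
        s = np.asarray(self.series.sigma_k_obs, float)
        # a point with an unusable error cannot be weighted; give it the
        # median weight rather than dropping the rate information
        s = np.where(np.isfinite(s) & (s > 0), s, np.nanmedian(s[s > 0]) if np.any(s > 0) else 1.0)
        p = lmfit.Parameters()
        p.add("k_cat", value=max(float(k.max()), 1e-9), min=1e-12, max=10.0)
        p.add("K_M", value=1.0, min=self.km_bounds[0], max=self.km_bounds[1])

        def resid(pars):
            return (mm_rate(c, pars["k_cat"], pars["K_M"]) - k) / s

        try:
            res = lmfit.minimize(resid, p, method="leastsq", scale_covar=False)
        except Exception:
            return MMFit(math.nan, math.nan, math.nan, math.nan, len(c), math.nan, False)
        err = {
            n: float(res.params[n].stderr)
            if res.params[n].stderr is not None
            else math.nan
            for n in ("k_cat", "K_M")
        }
        fit = MMFit(
            k_cat=float(res.params["k_cat"].value),
            K_M=float(res.params["K_M"].value),
            sigma_k_cat=err["k_cat"],
            sigma_K_M=err["K_M"],
            n_points=len(c),
            chisqr=float(np.sum(res.residual**2)),
            success=True,
        )
        return filter_kinetic_params(fit)


def fit_michaelis_menten(
    concentrations: Sequence[float],
    k_obs: Sequence[float],
    sigma_k_obs: Sequence[float],
) -> MMFit:
    """Convenience wrapper: build the model and fit."""
    series = ConcentrationSeries(
        tuple(concentrations), tuple(k_obs), tuple(sigma_k_obs)
    )
    return MichaelisMentenModel(series).fit()
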