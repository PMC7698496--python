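"""Weibull age-dependent survival for adult female longevity.

Adult survival is modelled as S(t) = exp(−(t/θ)^k): shape k controls how the
hazard changes with age (k > 1 senescent, increasing hazard; k = 1 recovers
the exponential, age-independent model) and scale θ sets the time scale in
days. Fitting is by maximum likelihood from a moment-matched start; when only
a printed (mean, SE, n) summary is available, moment matching alone supplies
(k, θ) for curve reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .life_tables import LifeTableError

__all__ = ["WeibullFit", "fit_weibull", "moment_match_weibull", "survival_curve"]


@dataclass(frozen=True)
class WeibullFit:
    shape: float  # k
    scale: float  # theta, days
    log_likelihood: float
    n: int
    converged: bool

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise LifeTableError("Weibull shape and scale must be positive")

    @property
    def mean(self) -> float:
        """Fitted mean lifespan θ·Γ(1 + 1/k), days."""
        return self.scale * special.gamma(1 + 1 / self.shape)

    @property
    def sd(self) -> float:
        k, th = self.shape, self.scale
        var = th**2 * (special.gamma(1 + 2 / k) - special.gamma(1 + 1 / k) ** 2)
        return math.sqrt(max(var, 0.0))


def _neg_log_likelihood(log_params: np.ndarray, t: np.ndarray,
                        censored: np.ndarray | None) -> float:
    k, th = np.exp(log_params)
    z = t / th
    log_surv = -(z**k)
    if censored is None:
        ll = np.sum(np.log(k / th) + (k - 1) * np.log(z) + log_surv)
    else:
        obs = ~censored
        ll = np.sum(
            np.where(
                obs,
                np.log(k / th) + (k - 1) * np.log(np.maximum(z, 1e-300)) + log_surv,
                log_surv,
            )
        )
    return -float(ll)


def fit_weibull(
    lifespans: Sequence[float],
    *,
    censored: Sequence[bool] | None = None,
) -> WeibullFit:
    """Maximum-likelihood Weibull fit to individual lifespans (days).

    Starts from the moment-matched (k, θ) and refines with Nelder–Mead on
    log parameters; the optimizer can only improve the likelihood, so the
    MLE never falls below the moment-matched start. Zero-variance samples
    (all deaths on the same day) have no finite MLE and raise.

    Parameters
    ----------
    lifespans : positive lifespans in days, n >= 3.
    censored : optional per-individual right-censoring flags; censored
        entries contribute S(t) instead of the density (all-deaths-observed
        studies leave this None).
    """
    t = np.asarray(lifespans, dtype=float)
    if t.size < 3:
        raise LifeTableError("need at least 3 lifespans to fit a Weibull")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise LifeTableError("all lifespans must be positive and finite")
    cens = None
    if censored is not None:
        cens = np.asarray(censored, dtype=bool)
        if cens.shape != t.shape:
            raise LifeTableError("censored flags must match lifespans in length")
        if cens.all():
            raise LifeTableError("cannot fit with every observation censored")
    m, s = float(t.mean()), float(t.std(ddof=1))
    if s == 0.0:
        raise LifeTableError(
            "zero-variance lifespans: Weibull shape is unidentified (k -> inf)"
        )
    try:
        k0, th0 = moment_match_weibull(m, s)
    except LifeTableError:
        k0, th0 = 1.0, m
    res = optimize.minimize(
        _neg_log_likelihood,
        x0=np.log([k0, th0]),
        args=(t, cens),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    k, th = np.exp(res.x)
    return WeibullFit(
        shape=float(k),
        scale=float(th),
        log_likelihood=-float(res.fun),
        n=int(t.size),
        converged=bool(res.success),
    )


def _cv_squared(k: float) -> float:
    g1 = special.gamma(1 + 1 / k)
    g2 = special.gamma(1 + 2 / k)
    return g2 / g1**2 - 1.0


def moment_match_weibull(
    mean: float, sd: float, *, k_bounds: tuple[float, float] = (0.1, 50.0)
) -> tuple[float, float]:
    """Solve mean = θ·Γ(1+1/k), sd² = θ²·[Γ(1+2/k) − Γ(1+1/k)²] for (k, θ).

    The squared coefficient of variation (sd/mean)² is strictly decreasing
    in k, so k is found by bracketed root finding; θ follows from the mean.
    Raises if no solution exists inside ``k_bounds``.
    """
    if mean <= 0 or sd <= 0:
        raise LifeTableError("moment matching requires mean > 0 and sd > 0")
    target = (sd / mean) ** 2
    lo, hi = k_bounds
    f_lo, f_hi = _cv_squared(lo) - target, _cv_squared(hi) - target
    if f_lo * f_hi > 0:
        raise LifeTableError(
            f"no Weibull shape in [{lo}, {hi}] matches cv = {sd / mean:.4g}"
        )
    k = optimize.brentq(lambda kk: _cv_squared(kk) - target, lo, hi, xtol=1e-12)
    theta = mean / special.gamma(1 + 1 / k)
    return float(k), float(theta)


def survival_curve(fit: WeibullFit, ages: Sequence[float]) -> np.ndarray:
    """S(t) = exp(−(t/θ)^k) evaluated at the given ages (days)."""
    a = np.asarray(ages, dtype=float)
    if np.any(a < 0):
        raise LifeTableError("ages must be non-negative")
    return np.exp(-((a / fit.scale) ** fit.shape))
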