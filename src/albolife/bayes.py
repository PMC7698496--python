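"""Posterior inference for binomial survival and Poisson duration parameters.

The analysis treats each survival fraction as a binomial proportion and each
duration/count mean as a Poisson rate, samples 10,000 values from each
posterior, and compares two groups by differencing their posterior draws and
measuring the two-sided tail probability of the difference distribution
around zero.

Priors (configurable): Beta(1, 1) for binomial proportions, a Jeffreys-type
Gamma(0.5, rate → 0) for Poisson means. With these, the posteriors are
conjugate — Beta(s + 1, n − s + 1) and Gamma(sum + 0.5, rate n) — and direct
sampling is the reference backend. A random-walk Metropolis backend (the
MCMC route) is provided and must agree with the conjugate form in
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

from .life_tables import LifeTableError, StageTransitionTable, STAGES, round_half_up

__all__ = [
    "PosteriorSample",
    "ComparisonResult",
    "fit_binomial_posterior",
    "fit_poisson_posterior",
    "compare_posteriors",
    "cumulative_survival",
    "cumulative_survival_posterior",
]

ParameterKind = Literal["binomial_p", "poisson_lambda"]

DEFAULT_N_DRAWS = 10_000


@dataclass(frozen=True)
class PosteriorSample:
    """A named posterior: draw vector plus provenance.

    Summary statistics (mean, sd, central 95% interval) are computed from the
    stored draws, so they are always consistent with them.
    """

    name: str
    kind: ParameterKind
    draws: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 1 or draws.size < 2:
            raise ValueError("draws must be a 1-D vector with at least 2 values")
        if self.kind == "binomial_p" and not (
            np.all(draws > 0) and np.all(draws < 1)
        ):
            raise ValueError("binomial_p draws must lie in (0, 1)")
        if self.kind == "poisson_lambda" and not np.all(draws > 0):
            raise ValueError("poisson_lambda draws must be positive")
        object.__setattr__(self, "draws", draws)

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws, [0.025, 0.975])
        return float(lo), float(hi)

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.draws, q)


@dataclass(frozen=True)
class ComparisonResult:
    """Posterior-difference comparison of a parameter between two groups.

    ``tail_probability`` is the probability of drawing zero from the
    difference distribution, operationalised two-sidedly as
    2·min(P(diff > 0), P(diff < 0)) clipped to [0, 1]; small values indicate
    the difference distribution is concentrated away from zero.
    """

    parameter_name: str
    group_labels: tuple[str, str]
    difference_draws: np.ndarray
    direction: int = field(init=False)
    tail_probability: float = field(init=False)

    def __post_init__(self) -> None:
        diff = np.asarray(self.difference_draws, dtype=float)
        object.__setattr__(self, "difference_draws", diff)
        p_pos = float(np.mean(diff > 0))
        p_neg = float(np.mean(diff < 0))
        tail = min(1.0, max(0.0, 2.0 * min(p_pos, p_neg)))
        object.__setattr__(self, "tail_probability", tail)
        object.__setattr__(self, "direction", int(np.sign(diff.mean())))

    @property
    def mean_difference(self) -> float:
        return float(self.difference_draws.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.difference_draws, [0.025, 0.975])
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_binomial_posterior(
    successes: int,
    trials: int,
    *,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int,
    prior: tuple[float, float] = (1.0, 1.0),
    backend: Literal["conjugate", "mcmc"] = "conjugate",
    name: str = "p",
) -> PosteriorSample:
    """Posterior of a binomial success probability.

    With prior Beta(a, b) the posterior is Beta(successes + a,
    trials − successes + b); the conjugate backend samples it directly, the
    ``mcmc`` backend runs random-walk Metropolis on logit(p) against the same
    likelihood and prior.
    """
    if not (isinstance(successes, (int, np.integer)) and isinstance(trials, (int, np.integer))):
        raise LifeTableError("successes and trials must be integers")
    if trials < 1:
        raise LifeTableError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise LifeTableError(
            f"successes ({successes}) must lie in [0, trials={trials}]"
        )
    a, b = prior
    if a <= 0 or b <= 0:
        raise LifeTableError("Beta prior parameters must be positive")
    alpha, beta = successes + a, trials - successes + b
    rng = np.random.default_rng(seed)
    if backend == "conjugate":
        draws = rng.beta(alpha, beta, size=n_draws)
        # guard the open-interval invariant at extreme counts
        eps = np.finfo(float).tiny
        draws = np.clip(draws, eps, 1 - 1e-16)
    elif backend == "mcmc":

        def logpost(theta: np.ndarray) -> np.ndarray:
            # theta = logit(p); includes the Jacobian of the transform
            return alpha * theta - (alpha + beta) * np.logaddexp(0.0, theta)

        theta = _metropolis(
            logpost,
            x0=special.logit((successes + a) / (trials + a + b)),
            step=2.5 / math.sqrt(alpha * beta / (alpha + beta)),
            n_draws=n_draws,
            rng=rng,
        )
        draws = special.expit(theta)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return PosteriorSample(
        name=name,
        kind="binomial_p",
        draws=draws,
        provenance={
            "successes": int(successes),
            "trials": int(trials),
            "prior": (float(a), float(b)),
            "seed": int(seed),
            "backend": backend,
        },
    )


def fit_poisson_posterior(
    observations: Sequence[int] | None = None,
    *,
    mean: float | None = None,
    n: int | None = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int,
    prior: tuple[float, float] = (0.5, 0.0),
    backend: Literal["conjugate", "mcmc"] = "conjugate",
    name: str = "lambda",
) -> PosteriorSample:
    """Posterior of a Poisson mean from observations or a (mean, n) summary.

    With prior Gamma(α, rate β) the posterior is Gamma(sum + α, rate n + β);
    the default α = 0.5, β = 0 is the Jeffreys prior. Summary-only input
    (printed mean with sample size) reconstructs sum = round-half-up(mean·n).
    """
    if observations is not None:
        obs = np.asarray(observations)
        if obs.size == 0:
            raise LifeTableError("observations must be non-empty")
        if np.any(obs < 0) or not np.all(obs == np.floor(obs)):
            raise LifeTableError("observations must be non-negative integers")
        total = int(obs.sum())
        n_obs = int(obs.size)
    else:
        if mean is None or n is None:
            raise LifeTableError("provide observations or both mean and n")
        if mean < 0 or n < 1:
            raise LifeTableError("summary requires mean >= 0 and n >= 1")
        total = round_half_up(mean * n)
        n_obs = int(n)
    alpha_prior, beta_prior = prior
    if alpha_prior <= 0 or beta_prior < 0:
        raise LifeTableError("Gamma prior requires alpha > 0 and rate >= 0")
    shape = total + alpha_prior
    rate = n_obs + beta_prior
    rng = np.random.default_rng(seed)
    if backend == "conjugate":
        draws = rng.gamma(shape, 1.0 / rate, size=n_draws)
        draws = np.maximum(draws, np.finfo(float).tiny)
    elif backend == "mcmc":

        def logpost(theta: np.ndarray) -> np.ndarray:
            # theta = log(lambda); Gamma(shape, rate) density plus Jacobian
            return shape * theta - rate * np.exp(theta)

        theta = _metropolis(
            logpost,
            x0=math.log(shape / rate),
            step=2.5 / math.sqrt(shape),
            n_draws=n_draws,
            rng=rng,
        )
        draws = np.exp(theta)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return PosteriorSample(
        name=name,
        kind="poisson_lambda",
        draws=draws,
        provenance={
            "sum": total,
            "n": n_obs,
            "prior": (float(alpha_prior), float(beta_prior)),
            "seed": int(seed),
            "backend": backend,
        },
    )


def _metropolis(logpost, x0: float, step: float, n_draws: int, rng, n_chains: int = 50,
                burn: int = 500, thin: int = 10) -> np.ndarray:
    """Random-walk Metropolis on an unconstrained scalar, vectorized across
    independent chains; returns n_draws pooled post-burn-in samples."""
    keep_per_chain = -(-n_draws // n_chains)  # ceil
    x = np.full(n_chains, float(x0)) + 0.1 * step * rng.standard_normal(n_chains)
    lp = logpost(x)
    kept = np.empty((keep_per_chain, n_chains))
    k = 0
    total_steps = burn + keep_per_chain * thin
    for i in range(total_steps):
        prop = x + step * rng.standard_normal(n_chains)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(n_chains)) < lp_prop - lp
        x = np.where(accept, prop, x)
        lp = np.where(accept, lp_prop, lp)
        if i >= burn and (i - burn) % thin == thin - 1:
            kept[k] = x
            k += 1
    return kept.reshape(-1)[:n_draws]


def compare_posteriors(
    sample_a: PosteriorSample,
    sample_b: PosteriorSample,
    *,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Difference the two posteriors draw-by-draw after independent shuffles.

    Shuffling breaks any accidental pairing between the two draw vectors so
    the elementwise difference samples the distribution of the difference of
    two independent parameters.
    """
    if sample_a.kind != sample_b.kind:
        raise LifeTableError(
            f"cannot compare {sample_a.kind} with {sample_b.kind}"
        )
    if sample_a.n_draws != sample_b.n_draws:
        raise LifeTableError("posterior samples must have equal n_draws")
    rng = np.random.default_rng(seed)
    diff = rng.permutation(sample_a.draws) - rng.permutation(sample_b.draws)
    return ComparisonResult(
        parameter_name=sample_a.name,
        group_labels=labels,
        difference_draws=diff,
    )


# ---------------------------------------------------------------------------
# Cumulative stage survival
# ---------------------------------------------------------------------------


def _chain_transitions(table: StageTransitionTable, from_stage: str, to_stage: str):
    i, j = STAGES.index(from_stage), STAGES.index(to_stage)
    if j < i:
        raise LifeTableError(f"{to_stage} precedes {from_stage}")
    pairs = [(STAGES[k], STAGES[k + 1]) for k in range(i, j)]
    out = []
    for a, b in pairs:
        t = table.transition(a, b)
        if not t.observed or t.trials == 0:
            raise LifeTableError(
                f"transition {a}->{b} was not observed for {table.population} "
                f"at {table.temperature} degC; cumulative survival undefined"
            )
        out.append(t)
    return out


def cumulative_survival(
    table: StageTransitionTable, from_stage: str, to_stage: str
) -> float:
    """Point estimate: product of per-stage empirical survival fractions.

    ``from_stage == to_stage`` gives the empty product 1.0. Raises if any
    intermediate transition was never observed.
    """
    frac = 1.0
    for t in _chain_transitions(table, from_stage, to_stage):
        frac *= t.fraction
    return frac


def cumulative_survival_posterior(
    table: StageTransitionTable,
    from_stage: str,
    to_stage: str,
    *,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int,
    prior: tuple[float, float] = (1.0, 1.0),
) -> PosteriorSample:
    """Posterior of cumulative survival as an elementwise product of
    independent per-stage Beta posterior draws."""
    chain = _chain_transitions(table, from_stage, to_stage)
    seeds = np.random.SeedSequence(seed).spawn(max(len(chain), 1))
    draws = np.ones(n_draws)
    for t, ss in zip(chain, seeds):
        stage_post = fit_binomial_posterior(
            t.successes,
            t.trials,
            n_draws=n_draws,
            seed=ss.generate_state(1)[0] % (2**31),
            prior=prior,
            name=f"{t.stage_from}->{t.stage_to}",
        )
        draws = draws * stage_post.draws
    draws = np.clip(draws, np.finfo(float).tiny, 1 - 1e-16)
    return PosteriorSample(
        name=f"{from_stage}->{to_stage}",
        kind="binomial_p",
        draws=draws,
        provenance={
            "population": table.population,
            "temperature": table.temperature,
            "stages": [f"{t.stage_from}->{t.stage_to}" for t in chain],
            "seed": int(seed),
            "prior": prior,
        },
    )
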