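"""Stochastic stage-structured cohort simulation with posterior uncertainty.

Projects a cohort of initial eggs (default 1000) through hatching, the
larval/pupal chain, and adult fecundity at one constant temperature. The
simulation is hierarchical: each replicate first draws the stage survival
probabilities from their Beta posteriors and the duration / fecundity means
from their Gamma posteriors (parameter uncertainty), then simulates every
individual Bernoulli/Poisson outcome under those parameters (demographic
stochasticity). Cross-replicate summaries therefore carry both sources of
uncertainty, which is what widens the adult-count interval far beyond the
pure binomial width.

Per emerging adult, development time = hatching time (Poisson) plus the
aggregate L1→Adult development duration (Poisson); the aggregate duration is
used rather than a sum of per-instar durations because the printed per-instar
means do not add up to the measured L1→Adult total. Lifetime fecundity is
females × (cycles per female) × (eggs per cycle), with per-replicate
posterior draws of both rates and Poisson individual-level noise; a
Weibull-lifespan-driven cycle-renewal variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import life_tables as lt
from .life_tables import LifeTableError, round_half_up
from .weibull import moment_match_weibull

__all__ = [
    "PosteriorSources",
    "CohortConfig",
    "CohortResult",
    "simulate_cohort",
    "expected_emergence_time",
]

#: transitions after hatching, in order
_CHAIN = lt.TRANSITIONS[1:]


@dataclass(frozen=True)
class PosteriorSources:
    """Sufficient statistics feeding the per-replicate posterior draws.

    All counts are integers: binomial (successes, trials) per stage
    transition; Poisson (total days, n individuals) for durations;
    (total cycles, n females) and (total eggs, n cycles) for fecundity
    (None where the temperature has no gonotrophic data).
    """

    temperature: float
    hatch: tuple[int, int]  # Egg->L1 (successes, trials)
    stages: tuple[tuple[int, int], ...]  # L1->L2 ... Pupa->Adult
    hatch_duration: tuple[int, int]  # (total days, n)
    dev_duration: tuple[int, int]  # L1->Adult aggregate (total days, n)
    cycles: tuple[int, int] | None = None
    eggs_per_cycle: tuple[int, int] | None = None
    cycle_duration: tuple[int, int] | None = None  # (total cycle-days, n cycles)
    longevity: tuple[float, float] | None = None  # (mean, sd) days

    def __post_init__(self) -> None:
        if len(self.stages) != len(_CHAIN):
            raise LifeTableError(
                f"need {len(_CHAIN)} post-hatch stage transitions, "
                f"got {len(self.stages)}"
            )
        for s, n in (self.hatch, *self.stages):
            if not (0 <= s <= n):
                raise LifeTableError(f"invalid counts (successes={s}, trials={n})")
        for tot, n in (self.hatch_duration, self.dev_duration):
            if tot < 0 or n < 1:
                raise LifeTableError("duration totals need total >= 0 and n >= 1")

    @classmethod
    def from_fixtures(
        cls, temperature: float, population: str = "temperate"
    ) -> "PosteriorSources":
        """Build sources for one temperature from the packaged life tables."""
        surv = lt.load_fixture(population, "stage_survival")
        durs = lt.load_fixture(population, "durations")
        if temperature not in surv:
            raise LifeTableError(
                f"no stage-survival fixture at {temperature} degC for {population}"
            )
        table = surv[temperature]
        hatch_t = table.transition("Egg", "L1")
        stages = []
        for a, b in _CHAIN:
            t = table.transition(a, b)
            if not t.observed:
                raise LifeTableError(
                    f"stage transition {a}->{b} not observed at "
                    f"{temperature} degC; cohort cannot be simulated"
                )
            stages.append((t.successes, t.trials))
        dur_map = durs.get(temperature, {})
        try:
            hd = dur_map[("Egg", "L1")]
            dd = dur_map[("L1", "Adult")]
        except KeyError as exc:
            raise LifeTableError(
                f"missing duration data {exc.args[0]} at {temperature} degC"
            ) from exc
        cycles = eggs = cyc_dur = None
        if population == "temperate":
            gono = lt.load_fixture(population, "gonotrophic")
            if temperature in gono:
                gt = gono[temperature]
                total_cycles = sum(gt.cycle_counts)
                total_eggs = round_half_up(
                    sum(int(r[1]) * float(r[5]) for r in gt.rows)
                )
                total_cycle_days = round_half_up(
                    sum(int(r[1]) * float(r[2]) for r in gt.rows)
                )
                cycles = (total_cycles, gt.n_females)
                eggs = (total_eggs, total_cycles)
                cyc_dur = (total_cycle_days, total_cycles)
        longevity = None
        if population == "temperate":
            longev = lt.load_fixture(population, "longevity")
            if temperature in longev:
                L = longev[temperature]
                longevity = (L.mean, L.sd)
        return cls(
            temperature=temperature,
            hatch=(hatch_t.successes, hatch_t.trials),
            stages=tuple(stages),
            hatch_duration=(hd.total_days, hd.n),
            dev_duration=(dd.total_days, dd.n),
            cycles=cycles,
            eggs_per_cycle=eggs,
            cycle_duration=cyc_dur,
            longevity=longevity,
        )


@dataclass(frozen=True)
class CohortConfig:
    temperature: float
    seed: int
    n_eggs: int = 1000
    n_replicates: int = 10_000
    sex_ratio: float = 0.5
    population: str = "temperate"
    parameter_uncertainty: bool = True
    weibull_fecundity: bool = False
    binomial_prior: tuple[float, float] = (1.0, 1.0)
    poisson_prior: tuple[float, float] = (0.5, 0.0)
    sources: PosteriorSources | None = None

    def __post_init__(self) -> None:
        if self.n_eggs < 1 or self.n_replicates < 1:
            raise LifeTableError("n_eggs and n_replicates must be >= 1")
        if not 0 <= self.sex_ratio <= 1:
            raise LifeTableError("sex_ratio must lie in [0, 1]")

    def resolve_sources(self) -> PosteriorSources:
        if self.sources is not None:
            return self.sources
        return PosteriorSources.from_fixtures(self.temperature, self.population)


def _summ(values: np.ndarray) -> dict:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {"mean": float("nan"), "ci_low": float("nan"), "ci_high": float("nan")}
    lo, hi = np.percentile(v, [2.5, 97.5])
    return {"mean": float(v.mean()), "ci_low": float(lo), "ci_high": float(hi)}


@dataclass
class CohortResult:
    """Per-replicate outcomes and cross-replicate summaries.

    ``stage_entrants`` has one row per replicate with the counts entering
    each stage (Egg, L1, ..., Adult), so stage-wise deaths are
    entrants[k] − entrants[k+1].
    """

    config: CohortConfig
    n_adults: np.ndarray
    n_females: np.ndarray
    mean_emergence_day: np.ndarray  # per replicate; NaN when no adults
    total_lifetime_eggs: np.ndarray  # NaN when fecundity sources absent
    stage_entrants: np.ndarray  # (n_replicates, 7) ints
    emergence_histogram: np.ndarray  # pooled adult emergence-day counts

    @property
    def pooled_emergence_mean(self) -> float:
        h = self.emergence_histogram
        n = h.sum()
        if n == 0:
            return float("nan")
        return float(np.dot(np.arange(h.size), h) / n)

    def pooled_emergence_quantile(self, q) -> np.ndarray:
        h = self.emergence_histogram
        cdf = np.cumsum(h) / h.sum()
        return np.searchsorted(cdf, np.atleast_1d(q), side="left").astype(float)

    def summary(self) -> dict:
        return {
            "n_adults": _summ(self.n_adults.astype(float)),
            "mean_emergence_day": _summ(self.mean_emergence_day),
            "total_lifetime_eggs": _summ(self.total_lifetime_eggs),
            "pooled_emergence": {
                "mean": self.pooled_emergence_mean,
                "ci_low": float(self.pooled_emergence_quantile(0.025)[0]),
                "ci_high": float(self.pooled_emergence_quantile(0.975)[0]),
            },
        }


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # substream r of the root seed: stable under partial reruns
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(r))))


def simulate_cohort(config: CohortConfig) -> CohortResult:
    """Run the hierarchical cohort simulation (see module docstring)."""
    src = config.resolve_sources()
    a0, b0 = config.binomial_prior
    al0, be0 = config.poisson_prior
    n_rep = config.n_replicates
    n_stages = len(_CHAIN)

    n_adults = np.zeros(n_rep, dtype=np.int64)
    n_females = np.zeros(n_rep, dtype=np.int64)
    mean_emerg = np.full(n_rep, np.nan)
    total_eggs = np.full(n_rep, np.nan)
    entrants = np.zeros((n_rep, n_stages + 2), dtype=np.int64)
    hist = np.zeros(1, dtype=np.int64)

    has_fec = src.cycles is not None and src.eggs_per_cycle is not None
    if config.weibull_fecundity:
        if src.longevity is None or src.cycle_duration is None:
            raise LifeTableError(
                "weibull_fecundity requires longevity and cycle-duration sources"
            )
        wk, wth = moment_match_weibull(*src.longevity)

    for r in range(n_rep):
        rng = _replicate_rng(config.seed, r)
        # --- parameter layer -------------------------------------------------
        if config.parameter_uncertainty:
            s, n = src.hatch
            p_hatch = rng.beta(s + a0, n - s + b0)
            p_stage = np.array(
                [rng.beta(s + a0, n - s + b0) for s, n in src.stages]
            )
            mu_hatch = rng.gamma(src.hatch_duration[0] + al0) / (
                src.hatch_duration[1] + be0
            )
            mu_dev = rng.gamma(src.dev_duration[0] + al0) / (
                src.dev_duration[1] + be0
            )
            if has_fec:
                lam_cyc = rng.gamma(src.cycles[0] + al0) / (src.cycles[1] + be0)
                lam_egg = rng.gamma(src.eggs_per_cycle[0] + al0) / (
                    src.eggs_per_cycle[1] + be0
                )
        else:
            s, n = src.hatch
            p_hatch = (s + a0) / (n + a0 + b0)
            p_stage = np.array(
                [(s + a0) / (n + a0 + b0) for s, n in src.stages]
            )
            mu_hatch = (src.hatch_duration[0] + al0) / (src.hatch_duration[1] + be0)
            mu_dev = (src.dev_duration[0] + al0) / (src.dev_duration[1] + be0)
            if has_fec:
                lam_cyc = (src.cycles[0] + al0) / (src.cycles[1] + be0)
                lam_egg = (src.eggs_per_cycle[0] + al0) / (
                    src.eggs_per_cycle[1] + be0
                )
        # --- individual layer ------------------------------------------------
        entrants[r, 0] = config.n_eggs
        alive = int(rng.binomial(config.n_eggs, p_hatch))
        entrants[r, 1] = alive
        for k in range(n_stages):
            alive = int(rng.binomial(alive, p_stage[k])) if alive else 0
            entrants[r, k + 2] = alive
        adults = alive
        n_adults[r] = adults
        if adults > 0:
            emergence = rng.poisson(mu_hatch, size=adults) + rng.poisson(
                mu_dev, size=adults
            )
            mean_emerg[r] = emergence.mean()
            counts = np.bincount(emergence)
            if counts.size > hist.size:
                hist = np.pad(hist, (0, counts.size - hist.size))
            hist[: counts.size] += counts
        females = int(rng.binomial(adults, config.sex_ratio)) if adults else 0
        n_females[r] = females
        if has_fec:
            if config.weibull_fecundity:
                # renewal variant: each female's cycle count is her Weibull
                # lifespan divided by a drawn mean cycle duration
                mu_cd = rng.gamma(src.cycle_duration[0] + al0) / (
                    src.cycle_duration[1] + be0
                )
                lives = (
                    wth * rng.weibull(wk, size=females) if females else np.empty(0)
                )
                n_cycles = int(np.floor(lives / max(mu_cd, 1e-9)).sum())
                total_eggs[r] = rng.poisson(n_cycles * lam_egg) if n_cycles else 0.0
            else:
                n_cycles = int(rng.poisson(females * lam_cyc)) if females else 0
                total_eggs[r] = (
                    rng.poisson(n_cycles * lam_egg) if n_cycles else 0.0
                )
    return CohortResult(
        config=config,
        n_adults=n_adults,
        n_females=n_females,
        mean_emergence_day=mean_emerg,
        total_lifetime_eggs=total_eggs,
        stage_entrants=entrants,
        emergence_histogram=hist,
    )


def expected_emergence_time(
    config_or_sources: CohortConfig | PosteriorSources,
    poisson_prior: tuple[float, float] = (0.5, 0.0),
) -> float:
    """Analytic companion: sum of posterior-mean stage durations, days.

    Posterior mean of a Poisson rate under Gamma(α, rate β) is
    (total + α)/(n + β); the emergence time is the hatching-time mean plus
    the aggregate L1→Adult development mean.
    """
    if isinstance(config_or_sources, CohortConfig):
        src = config_or_sources.resolve_sources()
        poisson_prior = config_or_sources.poisson_prior
    else:
        src = config_or_sources
    al0, be0 = poisson_prior
    mu_hatch = (src.hatch_duration[0] + al0) / (src.hatch_duration[1] + be0)
    mu_dev = (src.dev_duration[0] + al0) / (src.dev_duration[1] + be0)
    return float(mu_hatch + mu_dev)
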