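"""Individual-level synthetic experiments from known ground truth.

Emulates the laboratory design that produced the summary tables: replicate
cups of larvae monitored daily through the stage chain (binomial survival,
Poisson stage durations), and caged couples observed for adult lifespan
(Weibull) and sequential gonotrophic cycles (shifted-Poisson cycle duration,
Poisson egg batches) until death. Because the ground truth is known, every
inference stage of the pipeline can be tested by parameter recovery without
any external data.

A single root seed spawns one independent substream per component
(immature survival, stage durations, lifespans, gonotrophic process) via
``numpy.random.SeedSequence(seed).spawn``, so components can be regenerated
independently and all outputs are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .life_tables import (
    DurationSample,
    GonotrophicRecord,
    LifeTableError,
    LongevityTable,
    StageTransition,
    StageTransitionTable,
    STAGES,
    TRANSITIONS,
)

__all__ = ["GroundTruth", "generate_immature_experiment", "generate_adult_experiment"]


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for one temperature.

    Parameters
    ----------
    stage_survival : per-transition survival probabilities over
        Egg→L1, L1→L2, L2→L3, L3→L4, L4→Pupa, Pupa→Adult (all in [0, 1]).
    stage_duration_means : per-transition mean stage durations, days
        (Poisson; must be > 0 for every stage a survivor can traverse).
    weibull_shape, weibull_scale : adult female lifespan Weibull(k, θ), days.
    cycle_duration_means, cycle_duration_mins, cycle_eggs_means :
        per-cycle-index gonotrophic parameters; the last entry is reused
        beyond the listed cycles. Cycle duration is modelled as
        min + Poisson(mean − min) so durations respect the observed minimum.
    sex_ratio : probability an emerging adult is female.
    n_cups, larvae_per_cup : immature replicate design (10 × 10 by default).
    n_egg_batches, eggs_per_batch : egg-hatching design (12 cups of 10 eggs).
    independent_cycles : if True (default) cycle durations and egg counts are
        drawn independently across cycles within a female.
    """

    stage_survival: tuple[float, ...]
    stage_duration_means: tuple[float, ...]
    weibull_shape: float = 4.0
    weibull_scale: float = 70.0
    cycle_duration_means: tuple[float, ...] = (4.0,)
    cycle_duration_mins: tuple[int, ...] = (3,)
    cycle_eggs_means: tuple[float, ...] = (34.0,)
    sex_ratio: float = 0.5
    n_cups: int = 10
    larvae_per_cup: int = 10
    n_egg_batches: int = 12
    eggs_per_batch: int = 10
    independent_cycles: bool = True

    def __post_init__(self) -> None:
        ps = tuple(float(p) for p in self.stage_survival)
        lams = tuple(float(x) for x in self.stage_duration_means)
        if len(ps) != len(TRANSITIONS) or len(lams) != len(TRANSITIONS):
            raise LifeTableError(
                f"need {len(TRANSITIONS)} stage survival probabilities and "
                "duration means (Egg->L1 ... Pupa->Adult)"
            )
        if not all(math.isfinite(p) and 0 <= p <= 1 for p in ps):
            raise LifeTableError("stage survival probabilities must lie in [0, 1]")
        if not all(math.isfinite(x) and x >= 0 for x in lams):
            raise LifeTableError("stage duration means must be finite and >= 0")
        if not (self.weibull_shape > 0 and self.weibull_scale > 0):
            raise LifeTableError("Weibull shape and scale must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise LifeTableError("sex_ratio must lie in [0, 1]")
        if not (
            len(self.cycle_duration_means)
            == len(self.cycle_duration_mins)
            == len(self.cycle_eggs_means)
            >= 1
        ):
            raise LifeTableError("per-cycle parameter lists must align and be non-empty")
        for m, mn in zip(self.cycle_duration_means, self.cycle_duration_mins):
            if mn < 1 or m < mn:
                raise LifeTableError(
                    "cycle duration mean must be >= its minimum (>= 1 day)"
                )
        if any(e < 0 for e in self.cycle_eggs_means):
            raise LifeTableError("eggs-per-cycle means must be >= 0")
        object.__setattr__(self, "stage_survival", ps)
        object.__setattr__(self, "stage_duration_means", lams)

    def cycle_params(self, cycle_index: int) -> tuple[float, int, float]:
        """(duration mean, duration min, eggs mean) for 1-based cycle_index;
        the last listed cycle's parameters apply to all later cycles."""
        i = min(cycle_index, len(self.cycle_duration_means)) - 1
        return (
            self.cycle_duration_means[i],
            self.cycle_duration_mins[i],
            self.cycle_eggs_means[i],
        )


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_immature_experiment(
    truth: GroundTruth, seed: int, *, temperature: float = 25.0,
    population: str = "temperate",
) -> tuple[StageTransitionTable, list[DurationSample]]:
    """Simulate the egg-hatching and larval-rearing experiments.

    Eggs hatch Bernoulli(p_egg) in ``n_egg_batches`` cups of
    ``eggs_per_batch``; independently, ``n_cups`` cups of ``larvae_per_cup``
    fresh L1 are followed through the chain, each individual surviving
    transition s with probability p_s and, if surviving, spending
    Poisson(λ_s) days in the stage (the experiment re-seeds larval cups, so
    L1 trials are independent of the hatch counts). Returns the aggregate
    transition table and per-transition individual duration samples; also
    emits an aggregate L1→Adult duration sample (sum of stage days of the
    individuals that completed the whole chain).
    """
    rng_surv, rng_dur = _substreams(seed, 2)

    n_eggs = truth.n_egg_batches * truth.eggs_per_batch
    p_egg = truth.stage_survival[0]
    hatched = int(rng_surv.binomial(n_eggs, p_egg))
    hatch_days = rng_dur.poisson(truth.stage_duration_means[0], size=hatched)

    transitions = [
        StageTransition("Egg", "L1", n_eggs, hatched, observed=True)
    ]
    durations: list[DurationSample] = []
    if hatched > 0:
        durations.append(
            DurationSample(
                population=population,
                temperature=temperature,
                stage_from="Egg",
                stage_to="L1",
                observations=tuple(int(d) for d in hatch_days),
            )
        )

    n_larvae = truth.n_cups * truth.larvae_per_cup if hatched > 0 else 0
    # per-individual traversal, vectorized per transition
    alive = np.ones(n_larvae, dtype=bool)
    total_days = np.zeros(n_larvae, dtype=np.int64)
    for (a, b), p, lam in zip(
        TRANSITIONS[1:], truth.stage_survival[1:], truth.stage_duration_means[1:]
    ):
        trials = int(alive.sum())
        if trials == 0:
            transitions.append(StageTransition(a, b, 0, 0, observed=False))
            continue
        survive = np.zeros(n_larvae, dtype=bool)
        survive[alive] = rng_surv.random(trials) < p
        successes = int(survive.sum())
        transitions.append(StageTransition(a, b, trials, successes, observed=True))
        if successes > 0:
            days = rng_dur.poisson(lam, size=successes)
            total_days[survive] += days
            durations.append(
                DurationSample(
                    population=population,
                    temperature=temperature,
                    stage_from=a,
                    stage_to=b,
                    observations=tuple(int(d) for d in days),
                )
            )
        alive = survive
    if int(alive.sum()) > 0:
        durations.append(
            DurationSample(
                population=population,
                temperature=temperature,
                stage_from="L1",
                stage_to="Adult",
                observations=tuple(int(d) for d in total_days[alive]),
            )
        )
    table = StageTransitionTable(
        population=population, temperature=temperature, transitions=tuple(transitions)
    )
    return table, durations


def generate_adult_experiment(
    truth: GroundTruth,
    n_females: int,
    seed: int,
    *,
    temperature: float = 25.0,
    censor_at: int | None = None,
) -> tuple[LongevityTable, list[GonotrophicRecord]]:
    """Simulate caged couples: lifespans and sequential gonotrophic cycles.

    Each female draws a lifespan from Weibull(k, θ) rounded to integer days
    (minimum 1). Gonotrophic cycles accrue sequentially — cycle i lasts
    min_i + Poisson(mean_i − min_i) days and lays Poisson(eggs_i) eggs — and
    a cycle is recorded only if it completes within the lifespan.
    ``censor_at`` optionally right-censors lifespans at a study horizon
    (recorded lifespans are capped; default off, as all deaths were observed).
    """
    if n_females < 1:
        raise LifeTableError("n_females must be >= 1")
    rng_life, rng_gono = _substreams(seed, 2)
    raw = truth.weibull_scale * rng_life.weibull(truth.weibull_shape, size=n_females)
    lifespans = np.maximum(np.rint(raw).astype(int), 1)
    if censor_at is not None:
        lifespans = np.minimum(lifespans, int(censor_at))
    records = []
    for fid, life in enumerate(lifespans, start=1):
        cycles = []
        t = 0
        i = 1
        while True:
            mean_d, min_d, mean_e = truth.cycle_params(i)
            dur = min_d + int(rng_gono.poisson(mean_d - min_d))
            if t + dur > life:
                break
            eggs = int(rng_gono.poisson(mean_e))
            cycles.append((dur, eggs))
            t += dur
            i += 1
        records.append(
            GonotrophicRecord(
                female_id=fid, temperature=temperature, cycles=tuple(cycles)
            )
        )
    table = LongevityTable(
        temperature=temperature, lifespans=tuple(int(x) for x in lifespans)
    )
    return table, records
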