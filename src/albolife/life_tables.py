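"""Stage-structured life-table data model, packaged fixtures, and CSV I/O.

The central objects are per-temperature tables of *Aedes albopictus* life-cycle
observations: stage-transition survival counts over the chain
Egg → L1 → L2 → L3 → L4 → Pupa → Adult, developmental-time summaries,
adult female longevity, and per-cycle gonotrophic (blood meal → oviposition)
records. Two populations are distinguished: the ``temperate`` study colony
(northern Italy) and its ``subtropical`` reference (La Réunion), whose data
exist only as printed summaries.

Counts are integers throughout; durations are integer days (daily monitoring)
with summaries kept at one decimal. The packaged fixtures under ``data/``
encode the published summary tables (see ``data/MANIFEST.md`` for the count
reconstruction rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "STAGES",
    "LifeTableError",
    "StageTransition",
    "StageTransitionTable",
    "DurationSample",
    "LongevityTable",
    "GonotrophicRecord",
    "GonotrophicCycleTable",
    "round_half_up",
    "load_fixture",
    "read_life_table",
    "write_life_table",
]

#: Ordered life-stage vocabulary. Transitions run between consecutive stages.
STAGES: tuple[str, ...] = ("Egg", "L1", "L2", "L3", "L4", "Pupa", "Adult")

#: The six stage transitions, in developmental order.
TRANSITIONS: tuple[tuple[str, str], ...] = tuple(
    (STAGES[i], STAGES[i + 1]) for i in range(len(STAGES) - 1)
)

POPULATIONS = ("temperate", "subtropical")
TABLE_IDS = ("stage_survival", "durations", "longevity", "gonotrophic", "autogeny")


class LifeTableError(ValueError):
    """Raised on schema or invariant violations in life-table data."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 → 1).

    This is the documented rule for reconstructing integer success counts
    from printed survival fractions; Python's built-in banker's rounding
    would break the printed-fraction round trip (e.g. 74.4 → 74 but
    0.925·80 = 74.0 must not drop to 73 via ties-to-even at the half).
    """
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageTransition:
    stage_from: str
    stage_to: str
    trials: int
    successes: int
    observed: bool = True  # False: the stage was never reached ("not run")

    def __post_init__(self) -> None:
        if self.stage_from not in STAGES or self.stage_to not in STAGES:
            raise LifeTableError(
                f"unknown stage in transition {self.stage_from}->{self.stage_to}"
            )
        if STAGES.index(self.stage_to) != STAGES.index(self.stage_from) + 1:
            raise LifeTableError(
                f"non-consecutive transition {self.stage_from}->{self.stage_to}"
            )
        for name in ("trials", "successes"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise LifeTableError(
                    f"{name} must be a non-negative integer in "
                    f"{self.stage_from}->{self.stage_to}, got {v!r}"
                )
        if self.successes > self.trials:
            raise LifeTableError(
                f"successes ({self.successes}) > trials ({self.trials}) in "
                f"{self.stage_from}->{self.stage_to}"
            )

    @property
    def fraction(self) -> float:
        """Empirical survival fraction; NaN if the transition was not run."""
        if not self.observed or self.trials == 0:
            return float("nan")
        return self.successes / self.trials


@dataclass(frozen=True)
class StageTransitionTable:
    """Stage-wise survival counts for one population at one temperature.

    Invariants: within the larval chain (L1 onward) the trials of each
    observed transition equal the successes of the previous one; the Egg→L1
    trial count is independent (larval cups were re-seeded after hatching).
    """

    population: str
    temperature: float
    transitions: tuple[StageTransition, ...]

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise LifeTableError(f"unknown population {self.population!r}")
        object.__setattr__(self, "transitions", tuple(self.transitions))
        seen = [(t.stage_from, t.stage_to) for t in self.transitions]
        if len(set(seen)) != len(seen):
            raise LifeTableError("duplicate stage transition rows")
        self._validate_chain()

    def _validate_chain(self) -> None:
        prev: StageTransition | None = None
        for t in self.transitions:
            if (
                prev is not None
                and prev.observed
                and t.observed
                and prev.stage_from != "Egg"
                and t.trials != prev.successes
            ):
                raise LifeTableError(
                    f"larval chain mismatch at {t.stage_from}->{t.stage_to}: "
                    f"trials {t.trials} != previous successes {prev.successes}"
                )
            prev = t

    def transition(self, stage_from: str, stage_to: str) -> StageTransition:
        for t in self.transitions:
            if (t.stage_from, t.stage_to) == (stage_from, stage_to):
                return t
        raise LifeTableError(
            f"transition {stage_from}->{stage_to} not present for "
            f"{self.population} at {self.temperature} degC"
        )

    def fraction(self, stage_from: str, stage_to: str) -> float:
        return self.transition(stage_from, stage_to).fraction


@dataclass(frozen=True)
class DurationSample:
    """Developmental-time observations for one stage pair.

    Either individual integer-day ``observations`` or a printed ``summary``
    (mean, se, n) — exactly one form must be present. If observations are
    given, summary statistics are derived from them.
    """

    population: str
    temperature: float
    stage_from: str
    stage_to: str
    observations: tuple[int, ...] | None = None
    mean: float | None = None
    se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.observations is not None:
            obs = tuple(int(o) for o in self.observations)
            if len(obs) < 1 or any(o < 0 for o in obs):
                raise LifeTableError(
                    "duration observations must be non-negative integers"
                )
            object.__setattr__(self, "observations", obs)
            m = sum(obs) / len(obs)
            if len(obs) > 1:
                var = sum((o - m) ** 2 for o in obs) / (len(obs) - 1)
                se = math.sqrt(var / len(obs))
            else:
                se = 0.0
            for name, derived in (("mean", m), ("se", se), ("n", len(obs))):
                stated = getattr(self, name)
                if stated is not None and not math.isclose(
                    stated, derived, rel_tol=0, abs_tol=1e-9
                ):
                    raise LifeTableError(
                        f"stated {name}={stated} contradicts observations "
                        f"({derived})"
                    )
            object.__setattr__(self, "mean", m)
            object.__setattr__(self, "se", se)
            object.__setattr__(self, "n", len(obs))
        if self.mean is None or self.se is None or self.n is None:
            raise LifeTableError(
                "DurationSample needs observations or a full (mean, se, n) summary"
            )
        if self.n < 1 or self.mean < 0 or self.se < 0:
            raise LifeTableError(
                f"invalid duration summary (mean={self.mean}, se={self.se}, "
                f"n={self.n}) for {self.stage_from}->{self.stage_to}"
            )

    @property
    def total_days(self) -> int:
        """Integer total of observed days: sum(observations) or round(mean·n)."""
        if self.observations is not None:
            return int(sum(self.observations))
        return round_half_up(self.mean * self.n)


@dataclass(frozen=True)
class LongevityTable:
    """Adult female lifespans (days) at one temperature."""

    temperature: float
    lifespans: tuple[int, ...] | None = None
    mean: float | None = None
    se: float | None = None
    min: int | None = None
    max: int | None = None
    n: int | None = None
    population: str = "temperate"

    def __post_init__(self) -> None:
        if self.lifespans is not None:
            ls = tuple(int(x) for x in self.lifespans)
            if len(ls) < 1 or any(x <= 0 for x in ls):
                raise LifeTableError("lifespans must be positive integer days")
            object.__setattr__(self, "lifespans", ls)
            m = sum(ls) / len(ls)
            if len(ls) > 1:
                var = sum((x - m) ** 2 for x in ls) / (len(ls) - 1)
                se = math.sqrt(var / len(ls))
            else:
                se = 0.0
            object.__setattr__(self, "mean", m)
            object.__setattr__(self, "se", se)
            object.__setattr__(self, "min", min(ls))
            object.__setattr__(self, "max", max(ls))
            object.__setattr__(self, "n", len(ls))
        if None in (self.mean, self.se, self.min, self.max, self.n):
            raise LifeTableError(
                "LongevityTable needs lifespans or a full (mean, se, min, max, n)"
            )
        if not (self.min <= self.mean <= self.max):
            raise LifeTableError(
                f"longevity summary violates min <= mean <= max at "
                f"{self.temperature} degC"
            )
        if self.n < 1:
            raise LifeTableError("n must be >= 1")

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the standard error."""
        return self.se * math.sqrt(self.n)


@dataclass(frozen=True)
class GonotrophicRecord:
    """One female's ordered gonotrophic cycles as (duration days, eggs)."""

    female_id: int
    temperature: float
    cycles: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cyc = tuple((int(d), int(e)) for d, e in self.cycles)
        for d, e in cyc:
            if d < 1:
                raise LifeTableError(
                    f"cycle duration must be >= 1 day (female {self.female_id})"
                )
            if e < 0:
                raise LifeTableError(
                    f"negative egg count (female {self.female_id})"
                )
        object.__setattr__(self, "cycles", cyc)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def total_eggs(self) -> int:
        return sum(e for _, e in self.cycles)


@dataclass(frozen=True)
class GonotrophicCycleTable:
    """Per-cycle summary rows at one temperature (cycle-table form).

    ``rows`` are (cycle_index, n_females, duration_mean, duration_se,
    duration_min, eggs_mean, eggs_se) ordered by cycle index; n_females is
    non-increasing (a female contributing to cycle k completed all earlier
    cycles) and bounded by the number of females in the experiment.
    """

    temperature: float
    n_females: int
    rows: tuple[tuple, ...]
    population: str = "temperate"

    def __post_init__(self) -> None:
        rows = tuple(tuple(r) for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if self.n_females < 1:
            raise LifeTableError("n_females must be >= 1")
        prev_n = None
        prev_idx = 0
        for r in rows:
            idx, n = int(r[0]), int(r[1])
            if idx != prev_idx + 1:
                raise LifeTableError(f"cycle indices must be consecutive, got {idx}")
            if n > self.n_females:
                raise LifeTableError(
                    f"cycle {idx}: n={n} exceeds total females {self.n_females}"
                )
            if prev_n is not None and n > prev_n:
                raise LifeTableError(
                    f"cycle {idx}: n={n} increases over previous cycle ({prev_n})"
                )
            prev_idx, prev_n = idx, n

    @property
    def cycle_counts(self) -> tuple[int, ...]:
        return tuple(int(r[1]) for r in self.rows)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("albolife").joinpath("data", name))


def load_fixture(population: str, table_id: str):
    """Load a packaged fixture table.

    Parameters
    ----------
    population : {"temperate", "subtropical"}
    table_id : {"stage_survival", "durations", "longevity", "gonotrophic",
        "autogeny"}

    Returns
    -------
    dict mapping temperature (°C) to the typed table, except ``autogeny``
    which returns a DataFrame of bloodmeal-free layings.
    """
    if population not in POPULATIONS:
        raise LifeTableError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )
    if table_id not in TABLE_IDS:
        raise LifeTableError(
            f"unknown table id {table_id!r}; expected one of {TABLE_IDS}"
        )
    if table_id in ("longevity", "gonotrophic", "autogeny") and population != "temperate":
        raise LifeTableError(
            f"{table_id} fixtures exist only for the temperate population"
        )
    df = pd.read_csv(_data_path(f"{table_id}.csv"))
    df = df[df["population"] == population]
    if table_id == "autogeny":
        return df.reset_index(drop=True)
    out = {}
    for temp, grp in df.groupby("temperature_c"):
        if table_id == "stage_survival":
            out[float(temp)] = _survival_table_from_frame(population, float(temp), grp)
        elif table_id == "durations":
            out[float(temp)] = {
                (r.stage_from, r.stage_to): DurationSample(
                    population=population,
                    temperature=float(temp),
                    stage_from=r.stage_from,
                    stage_to=r.stage_to,
                    mean=float(r.mean_days),
                    se=float(r.se_days),
                    n=int(r.n),
                )
                for r in grp.itertuples()
            }
        elif table_id == "longevity":
            r = grp.iloc[0]
            out[float(temp)] = LongevityTable(
                temperature=float(temp),
                mean=float(r.mean_days),
                se=float(r.se_days),
                min=int(r.min_days),
                max=int(r.max_days),
                n=int(r.n),
            )
        elif table_id == "gonotrophic":
            rows = tuple(
                (
                    int(r.cycle_index),
                    int(r.n_females),
                    float(r.duration_mean),
                    float(r.duration_se),
                    int(r.duration_min),
                    float(r.eggs_mean),
                    float(r.eggs_se),
                )
                for r in grp.sort_values("cycle_index").itertuples()
            )
            out[float(temp)] = GonotrophicCycleTable(
                temperature=float(temp), n_females=20, rows=rows
            )
    return out


def _survival_table_from_frame(
    population: str, temperature: float, grp: pd.DataFrame
) -> StageTransitionTable:
    transitions = []
    for r in grp.itertuples():
        transitions.append(
            StageTransition(
                stage_from=r.stage_from,
                stage_to=r.stage_to,
                trials=int(r.trials),
                successes=int(r.successes),
                observed=(r.status == "observed"),
            )
        )
    order = {pair: i for i, pair in enumerate(TRANSITIONS)}
    transitions.sort(key=lambda t: order[(t.stage_from, t.stage_to)])
    return StageTransitionTable(
        population=population, temperature=temperature, transitions=tuple(transitions)
    )


# ---------------------------------------------------------------------------
# CSV round trip for user-supplied tables
# ---------------------------------------------------------------------------

_SURVIVAL_COLS = [
    "population",
    "temperature_c",
    "stage_from",
    "stage_to",
    "trials",
    "successes",
    "status",
]


def write_life_table(table: StageTransitionTable, path: str | Path) -> None:
    """Serialize a StageTransitionTable to CSV (UTF-8, header row)."""
    rows = [
        {
            "population": table.population,
            "temperature_c": table.temperature,
            "stage_from": t.stage_from,
            "stage_to": t.stage_to,
            "trials": t.trials,
            "successes": t.successes,
            "status": "observed" if t.observed else "not_run",
        }
        for t in table.transitions
    ]
    pd.DataFrame(rows, columns=_SURVIVAL_COLS).to_csv(path, index=False)


def read_life_table(path: str | Path) -> StageTransitionTable:
    """Read a single-population, single-temperature stage-survival CSV.

    Raises LifeTableError naming the offending row and field on schema
    violations (missing columns, non-integer counts, successes > trials,
    larval-chain mismatches).
    """
    df = pd.read_csv(Path(path))
    missing = set(_SURVIVAL_COLS) - set(df.columns)
    if missing:
        raise LifeTableError(f"missing columns: {sorted(missing)}")
    keys = df[["population", "temperature_c"]].drop_duplicates()
    if len(keys) != 1:
        raise LifeTableError(
            "expected a single (population, temperature) per file, got "
            f"{len(keys)} combinations"
        )
    for i, r in enumerate(df.itertuples()):
        for fieldname in ("trials", "successes"):
            v = getattr(r, fieldname)
            if float(v) != int(v):
                raise LifeTableError(
                    f"row {i}: {fieldname}={v!r} is not an integer count"
                )
        if int(r.successes) > int(r.trials):
            raise LifeTableError(
                f"row {i} ({r.stage_from}->{r.stage_to}): successes "
                f"{int(r.successes)} > trials {int(r.trials)}"
            )
    population = str(df["population"].iloc[0])
    temperature = float(df["temperature_c"].iloc[0])
    return _survival_table_from_frame(population, temperature, df)
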