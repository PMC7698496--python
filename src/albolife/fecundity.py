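"""Gonotrophic-cycle summaries and lifetime fecundity.

A gonotrophic cycle is the blood meal → egg maturation → oviposition loop of
an adult female; the number of cycles a female completes and the eggs laid
per cycle determine her lifetime fecundity. Cycle statistics are computed
from per-cycle summary rows (n females completing cycle k, mean duration,
mean eggs) or from individual female records, with exact rational arithmetic
for the count-based quantities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .life_tables import (
    GonotrophicCycleTable,
    GonotrophicRecord,
    LifeTableError,
)

__all__ = [
    "GonotrophicSummary",
    "summarize_gonotrophic",
    "records_to_cycle_table",
    "lifetime_fecundity",
]


@dataclass(frozen=True)
class GonotrophicSummary:
    """Cycle statistics for one temperature.

    - ``mean_cycles_per_female`` = total completed cycles / n_females
      (so a female contributes to cycle k's count only if she completed it).
    - weighted means weight each cycle row by its n, i.e. they are per-cycle
      averages over all completed cycles.
    - ``lifetime_eggs_per_female`` = Σ(n_k · eggs_k) / n_females.
    """

    temperature: float
    n_females: int
    mean_cycles_per_female: float
    per_cycle: tuple[tuple[int, int, float, float], ...]  # (idx, n, dur, eggs)
    weighted_mean_duration: float
    weighted_mean_eggs: float
    lifetime_eggs_per_female: float


def summarize_gonotrophic(
    source: GonotrophicCycleTable | Sequence[GonotrophicRecord],
    n_females: int | None = None,
) -> GonotrophicSummary:
    """Summarize gonotrophic data from a cycle table or female records.

    For a cycle table, ``n_females`` defaults to the table's own count; for
    records it defaults to the number of records (pass it explicitly if some
    females completed zero cycles but are not represented).
    """
    if isinstance(source, GonotrophicCycleTable):
        table = source
        nf = table.n_females if n_females is None else int(n_females)
        rows = [(int(r[0]), int(r[1]), float(r[2]), float(r[5])) for r in table.rows]
        temperature = table.temperature
    else:
        records = list(source)
        nf = len(records) if n_females is None else int(n_females)
        if records:
            temperature = records[0].temperature
        else:
            temperature = float("nan")
        table = records_to_cycle_table(records, n_females=nf)
        rows = [(int(r[0]), int(r[1]), float(r[2]), float(r[5])) for r in table.rows]
    if nf < 1:
        raise LifeTableError("n_females must be >= 1")

    total_cycles = sum(n for _, n, _, _ in rows)
    mean_cycles = Fraction(total_cycles, nf)
    if total_cycles > 0:
        w_dur = sum(n * d for _, n, d, _ in rows) / total_cycles
        w_eggs = sum(n * e for _, n, _, e in rows) / total_cycles
    else:
        w_dur = 0.0
        w_eggs = 0.0
    lifetime = sum(n * e for _, n, _, e in rows) / nf
    return GonotrophicSummary(
        temperature=temperature,
        n_females=nf,
        mean_cycles_per_female=float(mean_cycles),
        per_cycle=tuple(rows),
        weighted_mean_duration=float(w_dur),
        weighted_mean_eggs=float(w_eggs),
        lifetime_eggs_per_female=float(lifetime),
    )


def records_to_cycle_table(
    records: Sequence[GonotrophicRecord], n_females: int | None = None
) -> GonotrophicCycleTable:
    """Aggregate individual female records into per-cycle summary rows."""
    records = list(records)
    nf = len(records) if n_females is None else int(n_females)
    if nf < 1:
        raise LifeTableError("n_females must be >= 1")
    by_cycle: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for rec in records:
        for i, (dur, eggs) in enumerate(rec.cycles, start=1):
            by_cycle[i].append((dur, eggs))
    rows = []
    for idx in sorted(by_cycle):
        entries = by_cycle[idx]
        n = len(entries)
        durs = [d for d, _ in entries]
        eggs = [e for _, e in entries]
        rows.append(
            (
                idx,
                n,
                sum(durs) / n,
                0.0,  # SEs not tracked at the aggregate level
                min(durs),
                sum(eggs) / n,
                0.0,
            )
        )
    temperature = records[0].temperature if records else float("nan")
    return GonotrophicCycleTable(
        temperature=temperature, n_females=nf, rows=tuple(rows)
    )


def lifetime_fecundity(
    summary: GonotrophicSummary, n_adults: float, sex_ratio: float = 0.5
) -> float:
    """Total eggs expected from a cohort of adults.

    total = n_adults · sex_ratio · lifetime_eggs_per_female. The sex ratio
    (default 0.5) converts emerging adults to egg-laying females.
    """
    if n_adults < 0:
        raise LifeTableError("n_adults must be >= 0")
    if not 0 <= sex_ratio <= 1:
        raise LifeTableError("sex_ratio must lie in [0, 1]")
    return float(n_adults) * float(sex_ratio) * summary.lifetime_eggs_per_female
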