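# Fixture data

Life-table observations for *Aedes albopictus* reared at constant temperatures
(10, 15, 25, 30 °C), transcribed from a published laboratory study of a
temperate population (colony established from field collections in the
province of Trento, northern Italy) together with the printed summaries of its
subtropical reference population (La Réunion colony). All values are printed
summary cells; no individual-level raw data were deposited.

## stage_survival.csv

One row per stage transition per population per temperature, over the chain
Egg→L1, L1→L2, L2→L3, L3→L4, L4→Pupa, Pupa→Adult.

- `trials`, `successes`: integer counts. The source prints fractions ± SE and
  the number of individuals entering (temperate: 120 eggs and 100 L1 at every
  temperature; subtropical: 100/110/130/140 eggs at 10/15/25/30 °C and 80 L1).
  Success counts are reconstructed as round-half-up(fraction × trials), with
  trials chained down the larval stages (trials of L2→L3 = successes of
  L1→L2, and so on). Every reconstructed count reproduces the printed
  fraction at 2 decimal places. Egg→L1 trials are independent of L1 trials
  because larval cups were re-seeded with freshly hatched larvae.
- `printed_fraction`, `printed_se`: the fraction and standard error as
  printed (blank where the source prints a bare 0 or 1, or the transition was
  not run).
- `status`: `observed` (including "0 of n survived") or `not_run` (the stage
  was never reached, e.g. temperate 10 °C beyond L2→L3).

## durations.csv

Developmental-time summaries (mean ± SE, integer-day monitoring): time from
egg immersion to hatching (Egg→L1), per-instar durations, and the aggregate
L1→Adult development time. `n` is the number of individuals completing the
transition, taken from the reconstructed stage_survival counts. Note that the
per-instar means do not sum exactly to the printed L1→Adult aggregate (the
completing subsets differ per stage); the aggregate row is authoritative for
total development time. The 10 °C rows are sparse: only subtropical hatching
(2.0 ± 0.0) and the temperate L1→L2 transition (37.4 ± 0.7, "about 37 days")
were observed.

## longevity.csv

Adult female longevity (days) for the temperate population, 20 couples per
temperature, all deaths observed (no censoring): mean ± SE and min–max range.

## gonotrophic.csv

Per-cycle gonotrophic summaries for the temperate population at 25 and 30 °C:
number of females completing the cycle (`n_females`, non-increasing with cycle
index), cycle duration mean ± SE and observed minimum (days), and eggs laid
per cycle mean ± SE. 20 females per temperature.

## autogeny.csv

Three temperate females at 15 °C laid eggs (3, 7, 11) without a blood meal
(autogeny). Stored separately; excluded from gonotrophic summaries by default.
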