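# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Data model and count reconstruction

The immature life table is a chain of binomial transitions
Egg → L1 → L2 → L3 → L4 → Pupa → Adult. The published tables print survival
*fractions* with standard errors plus the number of individuals entering the
egg and L1 stages (temperate: 120 eggs, 100 L1 at every temperature;
subtropical: 100/110/130/140 eggs at 10/15/25/30 °C, 80 L1). Binomial
posteriors require integer counts, so successes are reconstructed as
round-half-up(fraction × trials), chaining trials down the larval stages
(trials of L2→L3 = successes of L1→L2, …). Every reconstructed count
reproduces its printed fraction at two decimals, and the cumulative
L1→Adult fraction recomputed from counts matches the printed column within
±0.005 at every populated temperature; both properties are tested. The
Egg→L1 trials are deliberately *not* chained into the larval stages because
the experiments re-seeded larval cups with fresh hatchlings.

The loader distinguishes "0 survived" (observed transition with zero
successes, e.g. temperate L2→L3 at 10 °C: 0 of 38) from "not run" (the
stage was never reached, e.g. temperate L3→L4 at 10 °C). Cumulative
survival across a chain containing a not-run transition is an error, not a
zero.

Durations are integer days (daily monitoring); printed summaries keep one
decimal. Each duration summary carries the n of individuals completing that
transition, taken from the reconstructed survival counts (e.g. the 25 °C
L1→Adult mean of 12.7 d is backed by the 81 adults that emerged). The
subtropical population exists as summary-level fixtures only; no
individual-level reconstruction is attempted beyond the integer counts.

One source-table ambiguity is resolved explicitly: the sparse 10 °C
duration row stores 37.4 ± 0.7 d as the temperate L1→L2 duration (the text
reports L1 larvae taking "about 37 days" to moult at 10 °C) and 2.0 ± 0.0 d
as the subtropical hatching time.

## Posterior inference

- Binomial survival: prior Beta(1, 1), posterior Beta(s + 1, n − s + 1).
- Poisson durations/counts: prior Gamma(½, rate → 0) (Jeffreys), posterior
  Gamma(Σx + ½, rate n). Summary-only inputs use Σx = round-half-up(mean·n).

Both priors are configurable; the defaults are minimal-information choices
whose posterior means stay within the printed standard errors of the summary
tables. Conjugate sampling is the reference backend. A random-walk
Metropolis backend (50 independent chains on the unconstrained scale,
500-step burn-in, thinning 10, proposal scaled to the posterior sd) honours
the MCMC formulation and is required by test to agree with the conjugate
distribution to Kolmogorov–Smirnov distance < 0.02 at 10,000 draws.

Group comparison differences the two draw vectors elementwise after an
independent shuffle of each (breaking any accidental pairing) and reports
the two-sided tail probability 2·min{P(Δ > 0), P(Δ < 0)}, clipped to
[0, 1]. Two-sidedness mirrors the symmetric way differences are reported in
both directions; a one-sided reading would halve the values. Null
calibration of the procedure (both groups drawn from the same binomial p,
500 repetitions) keeps the rate of tail ≤ 0.05 below 7%, and the median
tail probability is monotone non-increasing in the true group separation.

A caveat the package reports but does not resolve: printed duration SEs
(e.g. 12.7 ± 0.2 over n = 81) are narrower than the Poisson-implied
sampling SE (√(λ/n) ≈ 0.4), i.e. the raw data were under-dispersed relative
to Poisson. Posteriors here are Poisson-based by design; both the empirical
SE and the model-based posterior sd appear in the summary outputs, and no
agreement is forced.

## Weibull adult survival

Female lifespans follow S(t) = exp(−(t/θ)^k). With individual lifespans the
package fits (k, θ) by maximum likelihood: Nelder–Mead on (log k, log θ)
starting from the moment-matched values, converging tolerance 1e−8 on
parameters; the optimizer can only improve the likelihood, so the MLE never
falls below the moment-matched start (tested). Zero-variance samples have
no finite MLE (k → ∞) and raise rather than returning silently; an optional
right-censored likelihood is available behind a flag, off by default
because all deaths were observed in the study design.

Because the longevity table prints only mean ± SE and range for n = 20
females per temperature, curve reconstruction uses moment matching:
(sd/mean)² is strictly decreasing in k, so k solves
Γ(1+2/k)/Γ(1+1/k)² − 1 = cv² by Brent root finding on k ∈ [0.1, 50]
(xtol 1e−12), then θ = mean/Γ(1+1/k), with sd = SE·√n. Round trips are
accurate to 0.1%. All four temperature groups imply k > 1 (senescence),
with longevity maximal at 25 °C (64.5 d) — the qualitative shape and
ordering of the published survival curves; no printed parameter estimates
exist to anchor a sharper numeric check, so curve reproduction is asserted
as properties (S(0) = 1, monotone, formula agreement), not values.

## Gonotrophic fecundity

From per-cycle rows (cycle index k, n_k females completing it, mean
duration d_k, mean eggs e_k):

- cycles per female = Σn_k / n_females (exact rational arithmetic on
  counts: 158/20 = 7.9 at 25 °C, 35/20 = 1.75 at 30 °C);
- weighted means weight by n_k: Σn_k·x_k / Σn_k, reproducing the printed
  overall rows at one decimal (3.8 d / 34.3 eggs at 25 °C, 3.3 / 56.0 at
  30 °C);
- lifetime eggs per female = Σn_k·e_k / n_females (270.9 at 25 °C, 98.0 at
  30 °C).

This adopts the reading that n_k counts females *completing* (laying in)
cycle k, which is what makes Σn_k the total number of completed cycles. The
three autogenous layings at 15 °C (3, 7 and 11 eggs without a blood meal)
ship as a separate fixture and are excluded from cycle statistics by
default, since cycle statistics exist only for 25/30 °C. The adult sex
ratio is not measured in the tables; the default 0.5 links per-female
fecundity to cohort totals and is configurable.

## Cohort simulation

The simulator projects `n_eggs` (default 1000) through the life cycle at
one temperature, `n_replicates` times. Each replicate:

1. draws every stage survival probability from its Beta posterior and the
   hatching-time, development-time and fecundity means from their Gamma
   posteriors (parameter layer);
2. hatches each egg Bernoulli(p_hatch) and walks each hatchling through the
   five post-hatch transitions with Bernoulli survival (individual layer);
3. assigns each emerging adult a development time = Poisson(hatching mean)
   + Poisson(L1→Adult mean), counted from egg immersion;
4. draws females Binomial(adults, sex_ratio), total completed cycles
   Poisson(females · cycles-per-female), and total eggs
   Poisson(cycles · eggs-per-cycle).

Two deliberate structural choices:

- **Aggregate development time.** Emergence uses the measured L1→Adult
  aggregate duration (12.7 d at 25 °C), not the sum of per-instar means
  (15.4 d): the per-instar means are computed over different completing
  subsets and do not add up to the measured total. The analytic companion
  `expected_emergence_time` is the sum of the two posterior means
  (16.5 d at 25 °C, 10.8 d at 30 °C) and the pooled simulation mean is
  required to converge to it.
- **Hierarchical parameter draws.** Sampling parameters per replicate is
  what produces realistically wide cross-replicate intervals: with
  parameters fixed, 1000-egg adult counts are Binomial with an interval of
  roughly ±25 adults, while the Beta-posterior layer (dominated by the
  n = 120 hatch posterior) widens it to about 123–250 at 25 °C — matching
  the scale of the published 127–264 interval. A test verifies that the
  point-mass variant collapses to the binomial closed form and that the
  hierarchical interval is substantially wider.

Fecundity deliberately stays at the per-female-rate granularity (females ×
cycles × eggs with Poisson noise) rather than explicit day-by-day adult
aging; a Weibull-lifespan renewal variant (each female's cycle count = her
lifespan / drawn cycle duration) is available behind the
`weibull_fecundity` flag for exploration, but is not the default because
observed cycle counts (7.9 per female at 25 °C) are far below
lifespan/cycle-length (≈ 17), implying females stop cycling well before
death.

Replicate r uses the dedicated substream SeedSequence((seed, r)), so
results are independent of the number of replicates requested and partial
reruns are stable. Default problem sizes — 10,000 replicates in the library
API, 2000 in the orchestrated report and tests, 4000 in the acceptance
script — were chosen so the cross-replicate mean of every reported quantity
has a Monte-Carlo standard error at least an order of magnitude below its
tolerance band; at 2000 replicates the MC SE on mean adults is ≈ 0.8.

## Synthetic-data generator

The generator emulates the experimental design, not field conditions:
replicate cups of 10 larvae with independent Bernoulli survival and
Poisson(λ_s) integer-day stage durations; 20 caged couples with
Weibull-distributed female lifespans rounded to integer days (≥ 1); cycles
accruing sequentially until death, a cycle counted only if completed within
the lifespan. Cycle durations are modelled as minimum + Poisson(mean −
minimum) so they respect the observed per-cycle minimum durations while
staying in the Poisson family; a pure Poisson would generate impossible
sub-minimum cycles. Cycle durations and egg counts are independent across
cycles within a female (switchable assumption — the data do not constrain
within-female correlation). A single root seed spawns per-component
substreams, so survival counts and durations can be regenerated
independently; identical (truth, seed) gives byte-identical serialized
output.

What passing parameter-recovery tests on this generator shows: the
estimators are correct for data that genuinely follow the assumed
binomial/Poisson/Weibull structure at laboratory sample sizes. What it does
not show: robustness to overdispersion, within-female correlation,
density-dependent larval competition, or temperature fluctuation — all
absent from both the generator and the laboratory protocol it mimics.

## Numerical details and edge cases

- Round-half-up (floor(x + 0.5)) everywhere a printed summary is converted
  to an integer count; banker's rounding would break printed-fraction round
  trips at exact halves.
- Beta draws are clipped away from {0, 1} at machine precision to keep the
  open-interval invariant at extreme counts (e.g. 120/120).
- Tail probabilities are computed from the stored difference draws, so the
  smallest resolvable non-zero value is 2/n_draws; reported zeros mean
  "below resolution".
- Degenerate inputs fail loudly: successes > trials, larval-chain
  mismatches, gaps in a survival chain, zero-variance lifespans,
  all-censored samples, empty observation vectors.
- 10 °C is simulable for survival only up to L2 (later stages were never
  reached); requesting a full cohort there raises an error naming the first
  missing transition.

## Limitations

- Subtropical comparisons rest on reconstructed counts from printed
  fractions; sub-rounding information is unrecoverable.
- The Poisson duration model cannot represent the under-dispersion evident
  in the printed SEs; posterior intervals for duration means are therefore
  conservative.
- Survival-curve reconstruction from summaries is moment matching, not
  likelihood fitting; with n = 20 the implied (k, θ) carry substantial
  sampling uncertainty that the curves do not display.
- The cohort simulator models a single cohort at constant temperature; no
  multi-generation projection, density dependence, diapause, or thermal
  variation.
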