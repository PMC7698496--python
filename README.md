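# albolife

Temperature-dependent life-cycle analysis for *Aedes albopictus*, the Asian
tiger mosquito. The package is aimed at vector ecologists and modellers who
work with stage-structured laboratory life tables: survival fractions through
the immature chain (Egg → L1 → L2 → L3 → L4 → Pupa → Adult), developmental
times, adult female longevity, and gonotrophic-cycle fecundity, observed at
constant rearing temperatures (here 10, 15, 25 and 30 °C). It ships the
printed life tables of a temperate population (northern Italy) together with
the summaries of a subtropical reference population (La Réunion), and every
analysis also runs on user-supplied CSVs of the same schema.

## What it computes

- **Bayesian life-table inference.** Each stage survival fraction is a
  binomial proportion with posterior Beta(s + 1, n − s + 1) (uniform prior);
  each duration or count mean is a Poisson rate with posterior
  Gamma(Σx + ½, n) (Jeffreys prior). 10,000 posterior draws per parameter by
  direct conjugate sampling, with a random-walk Metropolis backend that must
  agree with the conjugate distribution (KS < 0.02).
- **Posterior-difference comparison.** Two groups are compared by
  differencing their posterior draws and reporting the two-sided tail
  probability 2·min{P(Δ > 0), P(Δ < 0)} of the difference distribution
  around zero.
- **Weibull adult survival.** Female longevity follows
  S(t) = exp(−(t/θ)^k); maximum-likelihood fitting for individual lifespans
  and moment matching (mean = θΓ(1+1/k), sd² = θ²[Γ(1+2/k) − Γ(1+1/k)²])
  when only summary statistics exist.
- **Gonotrophic fecundity.** Cycles per female, n-weighted per-cycle
  duration and egg means, and lifetime eggs per female from per-cycle
  summary rows or individual records.
- **Stochastic cohort simulation.** A hierarchical Monte-Carlo projection of
  1000 initial eggs: each replicate draws stage probabilities and duration /
  fecundity means from their posteriors, then simulates each individual's
  Bernoulli survival and Poisson development; outputs emerging adults,
  emergence times and lifetime egg production with cross-replicate 95%
  intervals that carry both parameter and demographic uncertainty.
- **Synthetic experiments.** A generator reproducing the laboratory design
  (replicate cups of 10 larvae, 20 caged couples) from known ground truth,
  so every estimator is testable by parameter recovery.

## Worked example

```python
import albolife as al

# survival through the immature chain at 15 degC
surv = al.load_fixture("temperate", "stage_survival")
frac = al.cumulative_survival(surv[15.0], "L1", "Adult")
print(f"L1->Adult at 15 degC: {frac:.2f}")          # 0.73

# is temperate hatching worse than subtropical at 25 degC?
st = al.load_fixture("subtropical", "stage_survival")
te_p = al.fit_binomial_posterior(28, 120, seed=2)    # 28/120 hatched
st_p = al.fit_binomial_posterior(64, 130, seed=3)    # 64/130 hatched
res = al.compare_posteriors(te_p, st_p, seed=4)
print(f"tail probability: {res.tail_probability:.4f}")  # 0.0000

# gonotrophic summary and cohort projection at 25 degC
gono = al.load_fixture("temperate", "gonotrophic")
s = al.summarize_gonotrophic(gono[25.0])
print(f"cycles/female: {s.mean_cycles_per_female}")  # 7.9
cfg = al.CohortConfig(temperature=25.0, seed=7, n_replicates=2000)
r = al.simulate_cohort(cfg).summary()
print(r["n_adults"])          # {'mean': 182.9525, 'ci_low': 123.0, 'ci_high': 250.0}
print(r["pooled_emergence"])  # {'mean': 16.518..., 'ci_low': 9.0, 'ci_high': 25.0}
```

Of 1000 eggs at 25 °C, about 183 adults (95% interval 123–250) emerge after
a pooled mean of 16.5 days (interval 9–25); the ~92 females among them lay
roughly 25,000 eggs over their lifetimes. At 30 °C emergence is faster
(10.8 days) and more adults emerge (~300), but total fecundity drops to
about 15,000 because females complete far fewer gonotrophic cycles (1.75 vs
7.9 on average).

The same pipeline is scriptable from the shell:

```bash
albolife report --outdir out/ --seed 42      # full analysis + figures
albolife simulate --temperature 30 --seed 1  # cohort projection JSON
albolife fecundity --temperature 25
```

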