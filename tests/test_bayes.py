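"""Conjugate/MCMC posterior machinery and the posterior-difference test."""

import numpy as np
import pytest
from scipy import stats

from albolife import (
    LifeTableError,
    compare_posteriors,
    cumulative_survival,
    cumulative_survival_posterior,
    fit_binomial_posterior,
    fit_poisson_posterior,
)


class TestBinomialPosterior:
    def test_matches_printed_survival_summary(self):
        """73/100 survivors: posterior mean ~ the printed fraction 0.73 and
        posterior sd ~ the printed SE 0.04."""
        post = fit_binomial_posterior(73, 100, seed=11)
        assert post.mean == pytest.approx(0.73, abs=0.01)
        assert post.sd == pytest.approx(0.04, abs=0.01)

    def test_zero_successes_closed_form(self):
        post = fit_binomial_posterior(0, 100, seed=12, n_draws=200_000)
        # Beta(1, 101) mean = 1/102; MC error ~ sd/sqrt(n)
        mc_se = post.sd / np.sqrt(post.n_draws)
        assert abs(post.mean - 1 / 102) < 3 * mc_se

    def test_quantiles_match_conjugate_beta(self):
        post = fit_binomial_posterior(28, 120, seed=13)
        qs = np.arange(0.01, 1.0, 0.01)
        sampled = post.quantile(qs)
        exact = stats.beta(29, 93).ppf(qs)
        assert np.max(np.abs(sampled - exact)) < 0.005

    @pytest.mark.parametrize("backend", ["conjugate", "mcmc"])
    def test_sampler_agrees_with_conjugate_distribution(self, backend):
        """KS distance between draws and the closed-form Beta < 0.02."""
        post = fit_binomial_posterior(73, 100, seed=14, backend=backend)
        ks = stats.kstest(post.draws, stats.beta(74, 28).cdf).statistic
        assert ks < 0.02

    def test_validation(self):
        with pytest.raises(LifeTableError):
            fit_binomial_posterior(101, 100, seed=1)
        with pytest.raises(LifeTableError):
            fit_binomial_posterior(5, 0, seed=1)

    def test_draws_in_open_interval(self):
        post = fit_binomial_posterior(120, 120, seed=15)
        assert np.all(post.draws > 0) and np.all(post.draws < 1)


class TestPoissonPosterior:
    def test_summary_input_matches_printed_mean(self):
        """Development L1->Adult at 25 degC: mean 12.7 over n=81 adults."""
        post = fit_poisson_posterior(mean=12.7, n=81, seed=21)
        assert post.provenance["sum"] == 1029
        assert post.mean == pytest.approx(12.7, abs=0.1)

    def test_single_observation_closed_form(self):
        post = fit_poisson_posterior([5], seed=22)
        exact_mean = 5.5  # Gamma(5.5, rate 1)
        mc_se = post.sd / np.sqrt(post.n_draws)
        assert abs(post.mean - exact_mean) < 3 * mc_se

    def test_quantiles_match_conjugate_gamma(self):
        post = fit_poisson_posterior(mean=36.8, n=10, seed=23)
        qs = np.arange(0.01, 1.0, 0.01)
        sampled = post.quantile(qs)
        exact = stats.gamma(a=368.5, scale=1 / 10).ppf(qs)
        assert np.max(np.abs(sampled / exact - 1)) < 0.005

    @pytest.mark.parametrize("backend", ["conjugate", "mcmc"])
    def test_sampler_agrees_with_conjugate_distribution(self, backend):
        post = fit_poisson_posterior(mean=12.7, n=81, seed=24, backend=backend)
        ks = stats.kstest(
            post.draws, stats.gamma(a=1029.5, scale=1 / 81).cdf
        ).statistic
        assert ks < 0.02

    def test_validation(self):
        with pytest.raises(LifeTableError):
            fit_poisson_posterior([], seed=1)
        with pytest.raises(LifeTableError):
            fit_poisson_posterior([1, -2], seed=1)
        with pytest.raises(LifeTableError):
            fit_poisson_posterior(seed=1)  # no data at all


class TestComparison:
    def test_self_comparison_is_null(self):
        post = fit_binomial_posterior(50, 100, seed=31)
        res = compare_posteriors(post, post, seed=32)
        assert res.tail_probability >= 0.9

    def test_te_vs_st_hatch_at_25(self):
        """Temperate hatch (28/120) is far below subtropical (64/130)."""
        te = fit_binomial_posterior(28, 120, seed=33)
        st_ = fit_binomial_posterior(64, 130, seed=34)
        res = compare_posteriors(te, st_, seed=35)
        assert res.tail_probability < 0.001
        assert res.direction == -1

    def test_separated_betas_match_normal_oracle(self):
        a = fit_binomial_posterior(499, 508, seed=36)  # Beta(500, 10)
        b = fit_binomial_posterior(9, 508, seed=37)  # Beta(10, 500)
        res = compare_posteriors(a, b, seed=38)
        assert res.tail_probability < 1e-4
        # normal approximation to the difference of the two Betas
        m = stats.beta(500, 10).mean() - stats.beta(10, 500).mean()
        s = np.sqrt(stats.beta(500, 10).var() + stats.beta(10, 500).var())
        assert stats.norm(m, s).cdf(0) < 1e-4

    def test_mismatched_kinds_rejected(self):
        a = fit_binomial_posterior(5, 10, seed=39)
        b = fit_poisson_posterior([3, 4], seed=40)
        with pytest.raises(LifeTableError):
            compare_posteriors(a, b)

    def test_type_i_error_control(self):
        """Null calibration: both groups from the same binomial p. The
        two-sided tail probability flags <=0.05 in at most 7% of runs."""
        rng = np.random.default_rng(41)
        n, p, reps = 100, 0.7, 500
        hits = 0
        for i in range(reps):
            sa = int(rng.binomial(n, p))
            sb = int(rng.binomial(n, p))
            pa = fit_binomial_posterior(sa, n, n_draws=4000, seed=1000 + i)
            pb = fit_binomial_posterior(sb, n, n_draws=4000, seed=5000 + i)
            if compare_posteriors(pa, pb, seed=i).tail_probability <= 0.05:
                hits += 1
        assert hits / reps <= 0.07

    def test_tail_probability_monotone_in_separation(self):
        """Larger true separation never raises the median tail probability
        (5-point grid, n fixed, common comparison seeds)."""
        n = 100
        medians = []
        for delta in (0.00, 0.03, 0.06, 0.09, 0.12):
            sa = round(n * (0.5 - delta / 2))
            sb = round(n * (0.5 + delta / 2))
            tails = []
            for i in range(40):
                pa = fit_binomial_posterior(sa, n, n_draws=4000, seed=100 + i)
                pb = fit_binomial_posterior(sb, n, n_draws=4000, seed=700 + i)
                tails.append(
                    compare_posteriors(pa, pb, seed=i).tail_probability
                )
            medians.append(float(np.median(tails)))
        assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))


class TestCumulativeSurvival:
    def test_known_products(self, te_survival):
        assert cumulative_survival(te_survival[15.0], "L1", "Adult") == pytest.approx(
            0.73, abs=0.005
        )
        assert cumulative_survival(te_survival[25.0], "L1", "Adult") == pytest.approx(
            0.81, abs=0.005
        )

    def test_empty_chain_is_one(self, te_survival):
        assert cumulative_survival(te_survival[25.0], "L2", "L2") == 1.0

    def test_gap_in_chain_names_missing_stage(self, te_survival):
        with pytest.raises(LifeTableError, match="L3->L4"):
            cumulative_survival(te_survival[10.0], "L1", "Adult")

    def test_posterior_product_consistent_with_point_estimate(self, te_survival):
        post = cumulative_survival_posterior(
            te_survival[25.0], "L1", "Adult", seed=51
        )
        point = cumulative_survival(te_survival[25.0], "L1", "Adult")
        # uniform priors shrink each stage toward 1/2; small downward shift
        assert abs(post.mean - point) < 0.05
        assert np.all(post.draws > 0) and np.all(post.draws < 1)


class TestParameterRecovery:
    def test_binomial_coverage_near_nominal(self):
        """95% equal-tailed intervals cover the generating p at 95% +- 5pp."""
        rng = np.random.default_rng(61)
        n, p, reps = 100, 0.7, 200
        covered = 0
        for i in range(reps):
            s = int(rng.binomial(n, p))
            post = fit_binomial_posterior(s, n, n_draws=4000, seed=2000 + i)
            lo, hi = post.ci95
            covered += lo <= p <= hi
        assert 0.90 <= covered / reps <= 1.0

    def test_poisson_coverage_near_nominal(self):
        rng = np.random.default_rng(62)
        lam, n, reps = 12.7, 81, 200
        covered = 0
        for i in range(reps):
            obs = rng.poisson(lam, size=n)
            post = fit_poisson_posterior(obs, n_draws=4000, seed=3000 + i)
            lo, hi = post.ci95
            covered += lo <= lam <= hi
        assert 0.90 <= covered / reps <= 1.0
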