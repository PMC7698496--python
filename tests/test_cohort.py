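"""Hierarchical cohort simulation: degenerate cases, conservation,
interval structure, and agreement with analytic companions."""

import numpy as np
import pytest
from scipy import stats

from albolife import (
    CohortConfig,
    LifeTableError,
    PosteriorSources,
    expected_emergence_time,
    simulate_cohort,
)


def _sources(hatch=(28, 120), stages=None, hd=(106, 28), dd=(1029, 81),
             cycles=(158, 20), eggs=(5417, 158)):
    if stages is None:
        stages = ((97, 100), (96, 97), (95, 96), (94, 95), (81, 94))
    return PosteriorSources(
        temperature=25.0,
        hatch=hatch,
        stages=tuple(stages),
        hatch_duration=hd,
        dev_duration=dd,
        cycles=cycles,
        eggs_per_cycle=eggs,
    )


class TestSources:
    def test_from_fixtures_matches_reconstructed_counts(self):
        src = PosteriorSources.from_fixtures(25.0)
        assert src.hatch == (28, 120)
        assert src.stages == ((97, 100), (96, 97), (95, 96), (94, 95), (81, 94))
        assert src.dev_duration == (1029, 81)  # 12.7 days x 81 adults
        assert src.cycles == (158, 20)
        assert src.eggs_per_cycle == (5417, 158)

    def test_unsimulable_temperature_names_missing_stage(self):
        with pytest.raises(LifeTableError, match="L3->L4"):
            PosteriorSources.from_fixtures(10.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(LifeTableError):
            _sources(hatch=(130, 120))


class TestSimulation:
    def test_deterministic_under_seed(self):
        cc = CohortConfig(temperature=25.0, seed=5, n_replicates=50)
        a, b = simulate_cohort(cc), simulate_cohort(cc)
        np.testing.assert_array_equal(a.n_adults, b.n_adults)
        np.testing.assert_array_equal(a.total_lifetime_eggs, b.total_lifetime_eggs)
        np.testing.assert_array_equal(a.emergence_histogram, b.emergence_histogram)

    def test_replicates_are_stable_substreams(self):
        """Replicate r's outcome does not depend on how many replicates run."""
        small = simulate_cohort(CohortConfig(temperature=25.0, seed=6, n_replicates=20))
        big = simulate_cohort(CohortConfig(temperature=25.0, seed=6, n_replicates=60))
        np.testing.assert_array_equal(small.n_adults, big.n_adults[:20])

    def test_degenerate_hatch_gives_zero_adults(self):
        cc = CohortConfig(
            temperature=25.0,
            seed=7,
            n_replicates=200,
            parameter_uncertainty=False,
            binomial_prior=(1e-9, 1.0),  # posterior mass at ~0 for 0/120
            sources=_sources(hatch=(0, 120)),
        )
        res = simulate_cohort(cc)
        assert np.all(res.n_adults == 0)
        assert np.isnan(res.pooled_emergence_mean)

    def test_stage_conservation(self):
        """Entrants at each stage equal survivors plus deaths of the
        previous stage, every replicate."""
        res = simulate_cohort(CohortConfig(temperature=25.0, seed=8, n_replicates=300))
        ent = res.stage_entrants
        assert np.all(np.diff(ent, axis=1) <= 0)
        assert np.all(ent[:, 0] == 1000)
        np.testing.assert_array_equal(ent[:, -1], res.n_adults)
        deaths = -np.diff(ent, axis=1)
        np.testing.assert_array_equal(
            ent[:, 1:] + deaths, ent[:, :-1]
        )

    def test_point_mass_interval_shrinks_to_binomial(self):
        """With parameter uncertainty off, adults ~ Binomial(n_eggs, q) where
        q is the product of fixed stage probabilities; the cross-replicate
        interval matches the binomial closed form."""
        cc = CohortConfig(
            temperature=25.0,
            seed=9,
            n_replicates=4000,
            parameter_uncertainty=False,
            sources=_sources(),
        )
        res = simulate_cohort(cc)
        a0, b0 = cc.binomial_prior
        q = np.prod(
            [(s + a0) / (n + a0 + b0) for s, n in ((28, 120), (97, 100),
                                                   (96, 97), (95, 96),
                                                   (94, 95), (81, 94))]
        )
        lo, hi = stats.binom.ppf([0.025, 0.975], 1000, q)
        s = res.summary()["n_adults"]
        assert abs(s["mean"] - 1000 * q) < 3 * np.sqrt(1000 * q * (1 - q) / 4000)
        assert abs(s["ci_low"] - lo) <= 3
        assert abs(s["ci_high"] - hi) <= 3

    def test_hierarchical_interval_is_wider_than_binomial(self):
        """Propagating Beta posterior uncertainty widens the adult-count
        interval well beyond the pure binomial width."""
        base = dict(temperature=25.0, seed=10, n_replicates=2000)
        wide = simulate_cohort(CohortConfig(**base)).summary()["n_adults"]
        narrow = simulate_cohort(
            CohortConfig(**base, parameter_uncertainty=False)
        ).summary()["n_adults"]
        assert (wide["ci_high"] - wide["ci_low"]) > 1.5 * (
            narrow["ci_high"] - narrow["ci_low"]
        )

    def test_mean_adults_monotone_in_stage_survival(self):
        """Improving one stage's survival never reduces mean adults
        (common random numbers across the grid)."""
        means = []
        for s_hatch in (24, 48, 72, 96, 120):
            cc = CohortConfig(
                temperature=25.0,
                seed=11,
                n_replicates=400,
                parameter_uncertainty=False,
                sources=_sources(hatch=(s_hatch, 120)),
            )
            means.append(simulate_cohort(cc).n_adults.mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_emergence_time_converges_to_analytic(self):
        cc = CohortConfig(temperature=25.0, seed=12, n_replicates=2000)
        res = simulate_cohort(cc)
        analytic = expected_emergence_time(cc)
        n_adults = res.emergence_histogram.sum()
        days = np.arange(res.emergence_histogram.size)
        mean = res.pooled_emergence_mean
        var = np.dot(res.emergence_histogram, (days - mean) ** 2) / n_adults
        mc_se = np.sqrt(var / n_adults)
        # parameter-layer noise adds a small extra term beyond individual MC
        assert abs(mean - analytic) < 3 * mc_se + 0.1

    def test_missing_fecundity_sources_yield_nan(self):
        cc = CohortConfig(
            temperature=25.0,
            seed=13,
            n_replicates=20,
            sources=_sources(cycles=None, eggs=None),
        )
        res = simulate_cohort(cc)
        assert np.all(np.isnan(res.total_lifetime_eggs))

    def test_weibull_fecundity_variant_runs(self):
        src = PosteriorSources.from_fixtures(25.0)
        cc = CohortConfig(
            temperature=25.0,
            seed=14,
            n_replicates=50,
            weibull_fecundity=True,
            sources=src,
        )
        res = simulate_cohort(cc)
        assert np.all(np.isfinite(res.total_lifetime_eggs))
        assert res.total_lifetime_eggs.mean() > 0


class TestAnalyticEmergence:
    def test_sum_of_posterior_mean_durations(self):
        """Hatch (3.8 d) plus L1->Adult development (12.7 d) at 25 degC gives
        16.5 days; 3.2 + 7.6 = 10.8 at 30 degC."""
        t25 = expected_emergence_time(CohortConfig(temperature=25.0, seed=0))
        t30 = expected_emergence_time(CohortConfig(temperature=30.0, seed=0))
        assert round(t25, 1) == 16.5
        assert round(t30, 1) == 10.8

    def test_degenerate_zero_durations(self):
        src = _sources(hd=(0, 28), dd=(0, 81))
        assert expected_emergence_time(src, poisson_prior=(1e-12, 0.0)) == pytest.approx(
            0.0, abs=1e-10
        )
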