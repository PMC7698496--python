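"""Pipeline orchestration: summary tables, comparison reports, and figures.

``run_full_analysis`` chains the whole analysis on the packaged fixtures (or
user CSVs of the same schema) and writes plain CSV intermediates plus a
manifest; figures are rendered from those CSVs so every plotted number is
testable without image comparison. All randomness flows from the single seed
recorded in the manifest, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import life_tables as lt
from .bayes import (
    compare_posteriors,
    cumulative_survival,
    cumulative_survival_posterior,
    fit_binomial_posterior,
    fit_poisson_posterior,
)
from .cohort import CohortConfig, expected_emergence_time, simulate_cohort
from .fecundity import summarize_gonotrophic
from .life_tables import LifeTableError
from .weibull import WeibullFit, moment_match_weibull, survival_curve

__all__ = ["RunConfig", "run_full_analysis", "plot_comparison"]

log = logging.getLogger("albolife")

#: quantities compared between the temperate and subtropical populations
_COMPARE_SURVIVAL = [("Egg", "L1"), ("L1", "Adult")]
_COMPARE_DURATION = [("Egg", "L1"), ("L1", "Adult")]


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    n_draws: int = 10_000
    n_replicates: int = 2000
    n_eggs: int = 1000
    sex_ratio: float = 0.5
    binomial_prior: tuple[float, float] = (1.0, 1.0)
    poisson_prior: tuple[float, float] = (0.5, 0.0)
    include_autogeny: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "outdir", Path(self.outdir))


def _subseed(root: int, *key: int) -> int:
    return int(
        np.random.SeedSequence((int(root), *key)).generate_state(1)[0] % (2**31)
    )


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline on the packaged fixtures.

    Writes, under ``config.outdir``:

    - ``survival_summary.csv`` — per transition: counts, fraction, Beta
      posterior mean/sd/95% CI, plus cumulative L1→Adult rows.
    - ``duration_summary.csv`` — per stage pair: printed mean ± SE and Gamma
      posterior mean/95% CI of the Poisson mean.
    - ``comparison_te_vs_st.csv`` — temperate-vs-subtropical posterior
      differences with tail probabilities.
    - ``weibull_fits.csv`` / ``survival_curves.csv`` — adult female Weibull
      parameters (moment-matched to the longevity summaries) and S(t) grids.
    - ``gonotrophic_summary.csv`` — cycles per female, weighted cycle
      statistics, lifetime eggs per female.
    - ``simulation_summary.csv`` — cohort simulation at 25 and 30 °C.
    - ``manifest.json`` — config, seed, package version, output inventory.
    - optionally ``comparison_panels.png`` via :func:`plot_comparison`.

    Any stage failure aborts with the stage name; outputs written so far are
    listed as partial in the raised error's message.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "survival_posteriors"
        surv_df, post_cache = _survival_summary(config)
        outputs["survival_summary"] = _write(surv_df, outdir / "survival_summary.csv")
        log.info("survival posteriors done (%.2fs)", time.perf_counter() - t0)

        stage = "duration_posteriors"
        dur_df, dur_cache = _duration_summary(config)
        outputs["duration_summary"] = _write(dur_df, outdir / "duration_summary.csv")

        stage = "comparisons"
        cmp_df = _comparison_table(config, post_cache, dur_cache)
        outputs["comparison"] = _write(cmp_df, outdir / "comparison_te_vs_st.csv")

        stage = "weibull"
        fits_df, curves_df = _weibull_outputs()
        outputs["weibull_fits"] = _write(fits_df, outdir / "weibull_fits.csv")
        outputs["survival_curves"] = _write(curves_df, outdir / "survival_curves.csv")

        stage = "gonotrophic"
        gono_df = _gonotrophic_summary(config)
        outputs["gonotrophic_summary"] = _write(
            gono_df, outdir / "gonotrophic_summary.csv"
        )

        stage = "simulation"
        sim_df = _simulation_summary(config)
        outputs["simulation_summary"] = _write(
            sim_df, outdir / "simulation_summary.csv"
        )

        if config.make_plots:
            stage = "plots"
            figs = plot_comparison(surv_df, dur_df, outdir)
            outputs.update(figs)

        stage = "manifest"
        manifest = {
            "package": "albolife",
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(config).items()
            },
            "outputs": {k: str(v.name) for k, v in outputs.items()},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        outputs["manifest"] = path
        log.info("pipeline complete (%.2fs)", time.perf_counter() - t0)
        return outputs
    except Exception as exc:
        partial = sorted(outputs)
        raise LifeTableError(
            f"pipeline failed at stage {stage!r}: {exc} (partial outputs: {partial})"
        ) from exc


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def _survival_summary(config: RunConfig):
    rows = []
    cache: dict[tuple, object] = {}
    for pop in ("temperate", "subtropical"):
        tables = lt.load_fixture(pop, "stage_survival")
        for temp, table in sorted(tables.items()):
            for t in table.transitions:
                if not t.observed or t.trials == 0:
                    continue
                post = fit_binomial_posterior(
                    t.successes,
                    t.trials,
                    n_draws=config.n_draws,
                    seed=_subseed(
                        config.seed,
                        1,
                        0 if pop == "temperate" else 1,
                        int(temp),
                        lt.STAGES.index(t.stage_from),
                    ),
                    prior=config.binomial_prior,
                    name=f"{t.stage_from}->{t.stage_to}",
                )
                cache[(pop, temp, t.stage_from, t.stage_to)] = post
                lo, hi = post.ci95
                rows.append(
                    {
                        "population": pop,
                        "temperature_c": temp,
                        "stage_from": t.stage_from,
                        "stage_to": t.stage_to,
                        "trials": t.trials,
                        "successes": t.successes,
                        "fraction": t.fraction,
                        "se": (
                            np.sqrt(t.fraction * (1 - t.fraction) / t.trials)
                            if t.trials
                            else np.nan
                        ),
                        "posterior_mean": post.mean,
                        "posterior_sd": post.sd,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            # cumulative L1->Adult where the chain is fully observed
            try:
                frac = cumulative_survival(table, "L1", "Adult")
                post = cumulative_survival_posterior(
                    table,
                    "L1",
                    "Adult",
                    n_draws=config.n_draws,
                    seed=_subseed(config.seed, 2, int(temp), 0 if pop == "temperate" else 1),
                    prior=config.binomial_prior,
                )
                cache[(pop, temp, "L1", "Adult")] = post
                lo, hi = post.ci95
                rows.append(
                    {
                        "population": pop,
                        "temperature_c": temp,
                        "stage_from": "L1",
                        "stage_to": "Adult",
                        "trials": table.transition("L1", "L2").trials,
                        "successes": np.nan,
                        "fraction": frac,
                        "se": np.nan,
                        "posterior_mean": post.mean,
                        "posterior_sd": post.sd,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            except LifeTableError:
                pass
    return pd.DataFrame(rows), cache


def _duration_summary(config: RunConfig):
    rows = []
    cache: dict[tuple, object] = {}
    for pop in ("temperate", "subtropical"):
        durs = lt.load_fixture(pop, "durations")
        for temp, dmap in sorted(durs.items()):
            for (a, b), d in dmap.items():
                post = fit_poisson_posterior(
                    mean=d.mean,
                    n=d.n,
                    n_draws=config.n_draws,
                    seed=_subseed(
                        config.seed,
                        3,
                        0 if pop == "temperate" else 1,
                        int(temp),
                        lt.STAGES.index(a),
                        lt.STAGES.index(b),
                    ),
                    prior=config.poisson_prior,
                    name=f"{a}->{b}",
                )
                cache[(pop, temp, a, b)] = post
                lo, hi = post.ci95
                rows.append(
                    {
                        "population": pop,
                        "temperature_c": temp,
                        "stage_from": a,
                        "stage_to": b,
                        "mean_days": d.mean,
                        "se_days": d.se,
                        "n": d.n,
                        "posterior_mean": post.mean,
                        "posterior_sd": post.sd,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    return pd.DataFrame(rows), cache


def _comparison_table(config: RunConfig, surv_cache, dur_cache) -> pd.DataFrame:
    rows = []
    specs = [("survival", surv_cache, _COMPARE_SURVIVAL),
             ("duration", dur_cache, _COMPARE_DURATION)]
    for kind_idx, (kind, cache, pairs) in enumerate(specs):
        for a, b in pairs:
            for temp in (10.0, 15.0, 25.0, 30.0):
                te = cache.get(("temperate", temp, a, b))
                st = cache.get(("subtropical", temp, a, b))
                if te is None or st is None:
                    continue
                res = compare_posteriors(
                    te,
                    st,
                    seed=_subseed(
                        config.seed, 4, kind_idx, lt.STAGES.index(a), int(temp)
                    ),
                    labels=("temperate", "subtropical"),
                )
                lo, hi = res.ci95
                rows.append(
                    {
                        "quantity": f"{kind}:{a}->{b}",
                        "temperature_c": temp,
                        "group_a": "temperate",
                        "group_b": "subtropical",
                        "mean_diff": res.mean_difference,
                        "ci_low": lo,
                        "ci_high": hi,
                        "tail_probability": res.tail_probability,
                        "direction": res.direction,
                    }
                )
    return pd.DataFrame(rows)


def _weibull_outputs():
    longev = lt.load_fixture("temperate", "longevity")
    fit_rows, curve_rows = [], []
    for temp, L in sorted(longev.items()):
        k, theta = moment_match_weibull(L.mean, L.sd)
        fit = WeibullFit(
            shape=k, scale=theta, log_likelihood=float("nan"), n=L.n, converged=True
        )
        fit_rows.append(
            {
                "temperature_c": temp,
                "shape_k": k,
                "scale_theta": theta,
                "mean_days": fit.mean,
                "sd_days": fit.sd,
                "n": L.n,
                "method": "moment_match",
            }
        )
        ages = np.arange(0, int(L.max * 1.5) + 1, 1)
        for age, s in zip(ages, survival_curve(fit, ages)):
            curve_rows.append(
                {"temperature_c": temp, "age_days": int(age), "survival": s}
            )
    return pd.DataFrame(fit_rows), pd.DataFrame(curve_rows)


def _gonotrophic_summary(config: RunConfig) -> pd.DataFrame:
    gono = lt.load_fixture("temperate", "gonotrophic")
    rows = []
    for temp, table in sorted(gono.items()):
        s = summarize_gonotrophic(table)
        rows.append(
            {
                "temperature_c": temp,
                "n_females": s.n_females,
                "mean_cycles_per_female": s.mean_cycles_per_female,
                "weighted_mean_duration": s.weighted_mean_duration,
                "weighted_mean_eggs": s.weighted_mean_eggs,
                "lifetime_eggs_per_female": s.lifetime_eggs_per_female,
            }
        )
    df = pd.DataFrame(rows)
    if config.include_autogeny:
        auto = lt.load_fixture("temperate", "autogeny")
        df.attrs["autogeny_note"] = (
            f"{len(auto)} bloodmeal-free layings at 15 degC excluded from cycles"
        )
    return df


def _simulation_summary(config: RunConfig) -> pd.DataFrame:
    rows = []
    for temp in (25.0, 30.0):
        cc = CohortConfig(
            temperature=temp,
            seed=_subseed(config.seed, 5, int(temp)),
            n_eggs=config.n_eggs,
            n_replicates=config.n_replicates,
            sex_ratio=config.sex_ratio,
            binomial_prior=config.binomial_prior,
            poisson_prior=config.poisson_prior,
        )
        res = simulate_cohort(cc)
        s = res.summary()
        rows.append(
            {
                "temperature_c": temp,
                "n_eggs": config.n_eggs,
                "n_replicates": config.n_replicates,
                "adults_mean": s["n_adults"]["mean"],
                "adults_ci_low": s["n_adults"]["ci_low"],
                "adults_ci_high": s["n_adults"]["ci_high"],
                "emergence_mean_day": s["pooled_emergence"]["mean"],
                "emergence_ci_low": s["pooled_emergence"]["ci_low"],
                "emergence_ci_high": s["pooled_emergence"]["ci_high"],
                "emergence_analytic": expected_emergence_time(cc),
                "lifetime_eggs_mean": s["total_lifetime_eggs"]["mean"],
                "lifetime_eggs_ci_low": s["total_lifetime_eggs"]["ci_low"],
                "lifetime_eggs_ci_high": s["total_lifetime_eggs"]["ci_high"],
            }
        )
    return pd.DataFrame(rows)


def plot_comparison(
    surv_df: pd.DataFrame, dur_df: pd.DataFrame, outdir: Path
) -> dict[str, Path]:
    """Point-and-interval comparison panels (mean ± 1.96·SE) for both
    populations: hatch fraction, L1→Adult fraction, hatch time, L1→Adult
    development time. Missing series drop the panel with a warning."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("Hatch fraction", surv_df, "Egg", "L1", "fraction", "se"),
        ("L1-Adult fraction", surv_df, "L1", "Adult", "fraction", "se"),
        ("Hatch time (days)", dur_df, "Egg", "L1", "mean_days", "se_days"),
        ("L1-Adult time (days)", dur_df, "L1", "Adult", "mean_days", "se_days"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    colors = {"temperate": "black", "subtropical": "tab:orange"}
    for ax, (title, df, a, b, vcol, secol) in zip(axes.ravel(), panels):
        sub = df[(df["stage_from"] == a) & (df["stage_to"] == b)]
        if sub.empty:
            log.warning("no data for panel %r; omitted", title)
            ax.set_visible(False)
            continue
        for pop, grp in sub.groupby("population"):
            grp = grp.sort_values("temperature_c")
            se = grp[secol].fillna(0.0)
            ax.errorbar(
                grp["temperature_c"],
                grp[vcol],
                yerr=1.96 * se,
                fmt="o",
                color=colors.get(pop, "gray"),
                label=pop,
                capsize=3,
            )
        ax.set_title(title)
        ax.set_xlabel("temperature (degC)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(outdir) / "comparison_panels.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return {"comparison_panels": path}
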