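"""Monte Carlo probabilistic sensitivity analysis and scenario orchestration.

Parameter uncertainty is propagated by sampling every calibrated coefficient
vector (per-destination transition logistics, state mortality odds, and the
calendar-trend log-odds) from a multivariate normal with its estimated
covariance, rebuilding the transition-probability set, and re-running the
projection.  Uncertainty intervals are empirical percentiles over draws,
computed per output series and year.  Draws are made at the coefficient
level so every derived probability stays internally consistent within a
draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import nearest_psd, rng_for
from .calibration import (ScenarioSpec, StateMortalityOdds, TwoYearTPTable,
                          TransitionModel, build_transition_set)
from .engine import PopulationState, project
from .trends import TrendEstimate, trend_from_coef


@dataclass
class CalibrationBundle:
    """Everything the projection engine needs, with coefficient covariances."""

    transition_model: TransitionModel
    tp_table: TwoYearTPTable
    prevalence: pd.DataFrame
    state_odds: StateMortalityOdds
    mortality_surface: pd.DataFrame
    trend: TrendEstimate
    population_grid: pd.DataFrame


@dataclass
class ParameterDraw:
    index: int
    transition_coefs: dict  # to_state -> Series
    state_log_or: pd.DataFrame
    trend_or: float


def sample_parameters(bundle: CalibrationBundle, rng: np.random.Generator,
                      index: int = 0) -> ParameterDraw:
    """One multivariate-normal draw of every calibrated coefficient vector."""
    coefs = {}
    for j, model in bundle.tp_table.models.items():
        mean = model["coef"].to_numpy()
        cov = model.get("cov")
        if cov is None:
            coefs[j] = model["coef"]
            continue
        covm, repaired = nearest_psd(cov.to_numpy())
        if repaired:
            warnings.warn(f"covariance for destination {j} repaired to PSD")
        draw = rng.multivariate_normal(mean, covm, method="eigh")
        coefs[j] = pd.Series(draw, index=model["coef"].index)

    lor = bundle.state_odds.log_or.copy()
    for cause, cov in bundle.state_odds.cov.items():
        names = [n for n in cov.index if n.startswith("state_")]
        if not names:
            continue
        sub, repaired = nearest_psd(cov.loc[names, names].to_numpy())
        if repaired:
            warnings.warn(f"state-mortality covariance ({cause}) repaired to PSD")
        mean = np.array([bundle.state_odds.log_or.loc[int(n.split("_")[1]), cause]
                         for n in names])
        draw = rng.multivariate_normal(mean, sub, method="eigh")
        for n, v in zip(names, draw):
            lor.loc[int(n.split("_")[1]), cause] = v

    # trend OR sampled on the log-odds scale from its CI-implied SE
    t = bundle.trend
    log_or = np.log(t.odds_ratio_per_year) + t.se_log * rng.standard_normal()
    return ParameterDraw(index=index, transition_coefs=coefs,
                         state_log_or=lor, trend_or=float(np.exp(log_or)))


def _project_draw(bundle: CalibrationBundle, scenario: ScenarioSpec,
                  initial: PopulationState, draw: ParameterDraw | None):
    if draw is None:
        tp = bundle.tp_table
        odds = bundle.state_odds
        trend = bundle.trend.odds_ratio_per_year
    else:
        tp = bundle.transition_model.margins(coef_override=draw.transition_coefs)
        odds = StateMortalityOdds(log_or=draw.state_log_or,
                                  cov=bundle.state_odds.cov)
        trend = draw.trend_or
    tset = build_transition_set(tp, trend, bundle.mortality_surface, odds,
                                scenario, bundle.prevalence)
    return project(initial, tset, scenario.horizon_year, bundle.population_grid)


@dataclass
class UncertaintyResult:
    percentiles: pd.DataFrame  # year x (series, p2.5/p50/p97.5)
    point: pd.DataFrame
    n_draws: int
    n_failed: int = 0


def run_psa(bundle: CalibrationBundle, scenario: ScenarioSpec,
            initial: PopulationState, n_draws: int = 1000,
            seed: int = 0, series=("dementia_count", "crude_prev_50", "std_prev"),
            max_failure_rate: float = 0.05) -> UncertaintyResult:
    """Monte Carlo PSA: ``n_draws`` full projections, empirical 2.5/50/97.5
    percentiles per output series and year.  Failed draws are logged and
    excluded; more than ``max_failure_rate`` failing is an error."""
    point = _project_draw(bundle, scenario, initial, None).summary.set_index("year")
    rng = rng_for(seed, 77)
    sims = {s: [] for s in series}
    failed = 0
    for i in range(n_draws):
        try:
            draw = sample_parameters(bundle, rng, index=i)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = _project_draw(bundle, scenario, initial, draw)
            summ = out.summary.set_index("year")
            for s in series:
                sims[s].append(summ[s])
        except Exception as err:
            failed += 1
            warnings.warn(f"draw {i} failed and was excluded: {err}")
    if failed > max_failure_rate * n_draws:
        raise RuntimeError(f"{failed}/{n_draws} PSA draws failed")
    pieces = {}
    for s in series:
        arr = pd.concat(sims[s], axis=1)
        pieces[(s, "p2.5")] = arr.quantile(0.025, axis=1)
        pieces[(s, "p50")] = arr.quantile(0.50, axis=1)
        pieces[(s, "p97.5")] = arr.quantile(0.975, axis=1)
    pct = pd.DataFrame(pieces)
    pct.columns = pd.MultiIndex.from_tuples(pct.columns, names=["series", "percentile"])
    return UncertaintyResult(percentiles=pct, point=point,
                             n_draws=n_draws - failed, n_failed=failed)


DEFAULT_SCENARIOS = ("estimated", "decline-2pct", "decline-1.1pct", "none", "cvd-freeze")


def run_scenarios(bundle: CalibrationBundle, initial: PopulationState,
                  scenarios=DEFAULT_SCENARIOS, horizon_year: int = 2040,
                  cvd_freeze_year: int = 2014, psa_draws: int = 0,
                  seed: int = 0) -> dict:
    """Run the scenario battery; returns {name: ProjectionOutput or
    (ProjectionOutput, UncertaintyResult)}."""
    out = {}
    for name in scenarios:
        if name == "cvd-freeze":
            spec = ScenarioSpec(incidence_trend="estimated",
                                cvd_freeze_year=cvd_freeze_year,
                                horizon_year=horizon_year, name="cvd-freeze")
        else:
            spec = ScenarioSpec(incidence_trend=name, horizon_year=horizon_year)
        proj = _project_draw(bundle, spec, initial, None)
        if psa_draws:
            unc = run_psa(bundle, spec, initial, n_draws=psa_draws, seed=seed)
            out[name] = (proj, unc)
        else:
            out[name] = proj
    return out


def scenario_comparison(results: dict) -> pd.DataFrame:
    """Tidy per-scenario dementia counts by year."""
    rows = []
    for name, res in results.items():
        proj = res[0] if isinstance(res, tuple) else res
        s = proj.summary
        for _, r in s.iterrows():
            rows.append((name, int(r["year"]), r["dementia_count"], r["std_prev"]))
    return pd.DataFrame(rows, columns=["scenario", "year", "dementia_count", "std_prev"])
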