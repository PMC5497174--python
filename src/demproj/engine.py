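"""Discrete-time multi-state cohort projection engine.

Iterates an age-sex-state population annually: apply one-year transition
probabilities, advance age by one year (the 100+ band is open), inject the
entering cohort of 35-year-olds into the healthy state, and accumulate
cause-specific deaths.  Derives counts, crude and age-standardised dementia
prevalence, deaths, and (period or cohort) life expectancy and
disability-free life expectancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (AGES, DEMENTIA_STATES, FUNCTIONAL_STATES, N_ALIVE,
                          SEXES, TransitionProbabilitySet)
from .cohort import BASE_YEAR

N_AGES = len(AGES)


@dataclass
class PopulationState:
    year: int
    counts: np.ndarray  # (n_ages, 2 sexes, 8 states)
    deaths_cum: np.ndarray = field(default_factory=lambda: np.zeros(2))  # cvd, noncvd
    entrants_cum: float = 0.0

    def __post_init__(self):
        if self.counts.shape != (N_AGES, 2, N_ALIVE):
            raise ValueError(f"counts must have shape {(N_AGES, 2, N_ALIVE)}")
        if (self.counts < 0).any() or not np.isfinite(self.counts).all():
            raise ValueError("counts must be non-negative and finite")

    @property
    def total_alive(self) -> float:
        return float(self.counts.sum())


def initialize_population(grid: pd.DataFrame, prevalence: pd.DataFrame,
                          year: int = BASE_YEAR) -> PopulationState:
    """counts = population x prevalence per (age, sex) cell."""
    base = grid[grid["year"] == year]
    pop = np.zeros((N_AGES, 2))
    for r in base.itertuples(index=False):
        pop[int(r.age) - AGES[0], 0 if r.sex == "m" else 1] = r.value
    prev = np.zeros((N_AGES, 2, N_ALIVE))
    for r in prevalence.itertuples(index=False):
        prev[int(r.age) - AGES[0], 0 if r.sex == "m" else 1, int(r.state) - 1] = r.prevalence
    sums = prev.sum(axis=2)
    if not np.allclose(sums[pop > 0], 1.0, atol=1e-6):
        raise ValueError("prevalences must be normalised over states")
    if (pop > 0).any() and np.any(sums[pop > 0] == 0):
        raise ValueError("prevalence missing for populated age cells")
    return PopulationState(year=year, counts=pop[:, :, None] * prev)


def step(state: PopulationState, tps_year: np.ndarray,
         entrants: tuple[float, float] = (0.0, 0.0)) -> PopulationState:
    """One annual iteration: transitions, ageing, entry cohort.

    ``tps_year``: (n_ages, 2, 8, 10) one-year probabilities with rows summing
    to one.  ``entrants``: numbers of (male, female) 35-year-olds entering
    the healthy state after ageing.
    """
    flows = np.einsum("asf,asft->ast", state.counts, tps_year)
    alive = flows[:, :, :N_ALIVE]
    deaths = flows[:, :, N_ALIVE:].sum(axis=(0, 1))
    if (alive < -1e-9).any():
        raise ValueError("negative counts after transition update; invalid TPs")
    aged = np.zeros_like(alive)
    aged[1:] = alive[:-1]
    aged[-1] += alive[-1]  # open 100+ band
    aged[0, 0, 0] += entrants[0]
    aged[0, 1, 0] += entrants[1]
    return PopulationState(
        year=state.year + 1,
        counts=np.maximum(aged, 0.0),
        deaths_cum=state.deaths_cum + deaths,
        entrants_cum=state.entrants_cum + float(sum(entrants)),
    )


@dataclass
class ProjectionOutput:
    """Per-year series of the projection, plus tidy accessors."""

    years: list
    state_counts: dict      # year -> (n_ages, 2, 8)
    deaths: pd.DataFrame    # year, cvd, noncvd (deaths during the year ending there)
    summary: pd.DataFrame   # per-year headline metrics
    standard_year: int = 2015

    def dementia_count(self, year: int) -> float:
        c = self.state_counts[year]
        return float(c[:, :, [s - 1 for s in DEMENTIA_STATES]].sum())

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for y in self.years:
            c = self.state_counts[y]
            for si, sex in enumerate(SEXES):
                for st in range(N_ALIVE):
                    rows.append((y, sex, f"state_{st+1}", c[:, si, st].sum()))
        return pd.DataFrame(rows, columns=["year", "sex", "metric", "value"])


def _prevalence(counts: np.ndarray, states, min_age: float, sex_idx=None) -> float:
    sel = [s - 1 for s in states]
    amask = AGES >= min_age
    sub = counts[amask]
    if sex_idx is not None:
        sub = sub[:, [sex_idx]]
    denom = sub.sum()
    return float(sub[:, :, sel].sum() / denom) if denom > 0 else np.nan


def _age_standardised_prevalence(counts, weights, states) -> float:
    """Weight age-sex-specific prevalences by a fixed standard population."""
    sel = [s - 1 for s in states]
    tot = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, counts[:, :, sel].sum(axis=2) / tot, 0.0)
    return float((p * weights).sum() / weights.sum())


def project(initial: PopulationState, tpset: TransitionProbabilitySet,
            horizon_year: int, entry_series: pd.DataFrame | None = None,
            standard_year: int | None = None,
            prevalence_min_age: float = 50.0) -> ProjectionOutput:
    """Run the engine from the initial year to ``horizon_year``.

    ``entry_series``: tidy (year, sex, age=35, value) rows for entering
    cohorts.  Age-standardised prevalence uses the modelled population of
    ``standard_year`` (default: the transition set's scenario setting).
    """
    years_avail = set(tpset.years())
    needed = set(range(initial.year, horizon_year))
    if not needed <= years_avail:
        raise ValueError("transition set does not cover the projection horizon")
    standard_year = standard_year or tpset.scenario.standard_population_year

    entrants = {}
    if entry_series is not None:
        e35 = entry_series[entry_series["age"] == 35]
        for (y, sex), grp in e35.groupby(["year", "sex"]):
            entrants[(int(y), sex)] = float(grp["value"].sum())

    states = {initial.year: initial.counts.copy()}
    deaths_rows = []
    cur = initial
    for y in range(initial.year, horizon_year):
        prev_deaths = cur.deaths_cum.copy()
        cur = step(cur, tpset[y], (entrants.get((y + 1, "m"), 0.0),
                                   entrants.get((y + 1, "f"), 0.0)))
        states[cur.year] = cur.counts.copy()
        d = cur.deaths_cum - prev_deaths
        deaths_rows.append((cur.year, d[0], d[1]))
    deaths = pd.DataFrame(deaths_rows, columns=["year", "deaths_cvd", "deaths_noncvd"])

    # standard population weights (modelled population at the standard year)
    std_counts = states.get(standard_year)
    if std_counts is None:
        std_counts = states[max(states)]
    weights = std_counts.sum(axis=2)

    rows = []
    for y in sorted(states):
        c = states[y]
        row = dict(
            year=y,
            alive=float(c.sum()),
            dementia_count=float(c[:, :, [s - 1 for s in DEMENTIA_STATES]].sum()),
            crude_prev_50=_prevalence(c, DEMENTIA_STATES, 50.0),
            crude_prev_65=_prevalence(c, DEMENTIA_STATES, 65.0),
            crude_prev_50_m=_prevalence(c, DEMENTIA_STATES, 50.0, 0),
            crude_prev_50_f=_prevalence(c, DEMENTIA_STATES, 50.0, 1),
            crude_prev_65_m=_prevalence(c, DEMENTIA_STATES, 65.0, 0),
            crude_prev_65_f=_prevalence(c, DEMENTIA_STATES, 65.0, 1),
            std_prev=_age_standardised_prevalence(c, weights, DEMENTIA_STATES),
            cvd_count=float(c[:, :, [1, 3, 6, 7]].sum()),
            functional_count=float(c[:, :, [s - 1 for s in FUNCTIONAL_STATES]].sum()),
        )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return ProjectionOutput(years=sorted(states), state_counts=states,
                            deaths=deaths, summary=summary,
                            standard_year=standard_year)


def life_expectancy(tpset: TransitionProbabilitySet, age: float, sex: str,
                    year: int, disability_states=FUNCTIONAL_STATES,
                    init_distribution: np.ndarray | None = None,
                    period: bool = False, max_years: int = 90) -> tuple[float, float]:
    """Cohort (or period) life expectancy and disability-free life expectancy.

    Simulates a unit mass from (age, sex, year) through calendar-varying
    transition probabilities (held at the final available year beyond the
    horizon; ``period=True`` freezes them at ``year``).  LE sums expected
    person-years alive after each annual step; DFLE counts only the states
    without functional impairment.
    """
    if not AGES[0] <= age <= AGES[-1]:
        raise ValueError(f"starting age {age} outside the model grid")
    si = 0 if sex == "m" else 1
    ai = int(age) - AGES[0]
    free = [s - 1 for s in range(1, N_ALIVE + 1) if s not in disability_states]
    mass = np.zeros((N_AGES, N_ALIVE))
    if init_distribution is None:
        mass[ai, 0] = 1.0
    else:
        mass[ai] = init_distribution / init_distribution.sum()
    last = max(tpset.years())
    le = dfle = 0.0
    y = year
    for _ in range(max_years):
        tp = tpset[min(year if period else y, last)][:, si]  # (ages, 8, 10)
        moved = np.einsum("af,aft->at", mass, tp[:, :, :N_ALIVE])
        aged = np.zeros_like(mass)
        aged[1:] = moved[:-1]
        aged[-1] += moved[-1]
        mass = aged
        le += mass.sum()
        dfle += mass[:, free].sum()
        y += 1
        if mass.sum() < 1e-12:
            break
    return float(le), float(dfle)
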