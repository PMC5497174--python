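"""Calibration of the multi-state cohort model from panel data.

Maps ascertained person-wave histories onto the eight-state structure
(cardiovascular disease x cognitive impairment x dementia x functional
impairment, plus two absorbing death states), estimates pooled two-year
transition probabilities by logistic regression, converts them to one-year
probabilities, fits smoothed starting prevalences by single year of age,
estimates per-state mortality odds ratios, projects population mortality
rates forward, and assembles the calendar-year-indexed one-year transition
probability set the projection engine consumes.

State labelling (the only one consistent with "states 6 and 7 are dementia;
states 5-8 are functional impairment; dementia implies functional
impairment"):

    1 healthy                 5 functional impairment, no dementia, no CVD
    2 CVD only                6 dementia, no CVD
    3 CIND only               7 dementia with CVD
    4 CIND with CVD           8 functional impairment, no dementia, with CVD
    9 CVD death              10 non-CVD death
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.special import expit, logit as slogit

from ._utils import check_prob
from .cohort import AGE_BANDS, BASE_YEAR, band_label
from .trends import TrendEstimate

N_ALIVE = 8
DEATH_CVD = 9
DEATH_NONCVD = 10
AGES = np.arange(35, 101)  # single year of age; 100 is the open 100+ band
SEXES = ("m", "f")

STATE_FLAGS = {  # state -> (has_cvd, has_cind, has_dementia, has_funcimp)
    1: (False, False, False, False),
    2: (True, False, False, False),
    3: (False, True, False, False),
    4: (True, True, False, False),
    5: (False, False, False, True),
    6: (False, False, True, True),
    7: (True, False, True, True),
    8: (True, False, False, True),
}

DEMENTIA_STATES = (6, 7)
FUNCTIONAL_STATES = (5, 6, 7, 8)
CIND_STATES = (3, 4)
CVD_STATES = (2, 4, 7, 8)


@dataclass(frozen=True)
class HealthState:
    index: int

    @property
    def has_cvd(self) -> bool:
        return self.index in CVD_STATES

    @property
    def has_cind(self) -> bool:
        return self.index in CIND_STATES

    @property
    def has_dementia(self) -> bool:
        return self.index in DEMENTIA_STATES

    @property
    def has_functional_impairment(self) -> bool:
        return self.index in FUNCTIONAL_STATES


def allowed_transition(i: int, j: int, cind_recovery: bool = True,
                       direct_fi_to_dementia: bool = True) -> bool:
    """Progressive-disease rules: no dementia recovery, no loss of CVD.

    CIND and functional-impairment recovery are allowed (transience is real
    in panel data).  ``direct_fi_to_dementia`` permits 5->6 and 8->7.
    """
    if j in (DEATH_CVD, DEATH_NONCVD):
        return True
    if (i in CVD_STATES) and (j not in CVD_STATES):
        return False
    if (i in DEMENTIA_STATES) and (j not in DEMENTIA_STATES):
        return False
    if not cind_recovery and i in CIND_STATES and j in (1, 2):
        return False
    if not direct_fi_to_dementia and i in (5, 8) and j in DEMENTIA_STATES:
        return False
    return True


def derive_states(panel: pd.DataFrame, statuses: pd.DataFrame,
                  cognitive_flags: pd.DataFrame,
                  functional_flags: pd.DataFrame,
                  analysis_waves: tuple = (1, 2, 3, 4, 5, 6)) -> pd.DataFrame:
    """Per person-wave health state (1-8) from ascertained flags.

    Dementia takes precedence over contradictory flags (a dementia case
    without current cognitive-impairment flags is still in a dementia state).
    """
    st = statuses.set_index("person_id")
    df = panel[panel["wave"].isin(analysis_waves)][
        ["person_id", "wave", "year", "age", "sex", "cvd_status",
         "death_year", "death_cause", "entry_year"]].copy()
    df = df.merge(cognitive_flags[["person_id", "wave", "cognitive_impairment"]],
                  on=["person_id", "wave"], how="left")
    df = df.merge(functional_flags[["person_id", "wave", "functional_impairment"]],
                  on=["person_id", "wave"], how="left")
    aw = pd.to_numeric(df["person_id"].map(st["ascertainment_wave"]), errors="coerce")
    is_case = df["person_id"].map(st["is_case"]).fillna(False).astype(bool)
    dem = is_case & (df["wave"] >= aw)
    cvd = df["cvd_status"].fillna(0).astype(bool)
    fi = df["functional_impairment"].fillna(False).astype(bool) | dem
    cind = df["cognitive_impairment"].fillna(False).astype(bool)
    state = np.select(
        [dem & cvd, dem, fi & cvd, fi, cind & cvd, cind, cvd],
        [7, 6, 8, 5, 4, 3, 2],
        default=1,
    )
    df["state"] = state
    return df[["person_id", "wave", "year", "age", "sex", "state",
               "death_year", "death_cause", "entry_year"]]


def build_transition_pairs(state_panel: pd.DataFrame) -> pd.DataFrame:
    """Pooled two-year wave pairs: each person contributes one row per epoch
    observed (destination = next-wave state, or a death state if death
    occurred inside the epoch; otherwise the pair is dropped as censored)."""
    sp = state_panel.sort_values(["person_id", "wave"])
    nxt = sp.groupby("person_id")[["wave", "state"]].shift(-1)
    pairs = sp.copy()
    pairs["to_state"] = np.where(nxt["wave"] == pairs["wave"] + 1, nxt["state"], np.nan)
    death_in = (pairs["death_year"].notna()
                & (pairs["death_year"] > pairs["year"])
                & (pairs["death_year"] <= pairs["year"] + 2))
    pairs.loc[death_in & (pairs["death_cause"] == "cvd"), "to_state"] = DEATH_CVD
    pairs.loc[death_in & (pairs["death_cause"] == "noncvd"), "to_state"] = DEATH_NONCVD
    pairs = pairs[pairs["to_state"].notna()].copy()
    pairs["to_state"] = pairs["to_state"].astype(int)
    pairs["from_state"] = pairs["state"].astype(int)
    pairs["age_mid"] = pairs["age"] + 1.0
    pairs["female"] = (pairs["sex"] == "f").astype(float)
    return pairs[["person_id", "wave", "year", "age_mid", "female", "sex",
                  "from_state", "to_state"]]


@dataclass
class TwoYearTPTable:
    """Fitted destination models and their marginal two-year probabilities."""

    margins: pd.DataFrame  # columns: sex, age, from_state, to_state, P
    models: dict  # to_state -> dict(coef=Series, cov=DataFrame)
    reference_year: int = BASE_YEAR

    def matrix(self) -> np.ndarray:
        """(n_ages, 2, 8, 10) array of two-year probabilities."""
        arr = np.zeros((len(AGES), 2, N_ALIVE, N_ALIVE + 2))
        m = self.margins
        ai = m["age"].to_numpy(int) - AGES[0]
        si = (m["sex"] == "f").to_numpy(int)
        arr[ai, si, m["from_state"].to_numpy(int) - 1,
            m["to_state"].to_numpy(int) - 1] = m["P"].to_numpy()
        return arr


class TransitionModel:
    """Pooled destination-specific logistic transition fits.

    One logistic model per destination state with terms for age, sex, their
    interaction and the initial state; transitions into the CIND states add
    age-squared and its sex interaction.  Margins are evaluated on a single
    year-of-age grid and renormalised so each row (with the stay probability
    as residual) sums to one.
    """

    def __init__(self, cind_recovery: bool = True, direct_fi_to_dementia: bool = True):
        self.cind_recovery = cind_recovery
        self.direct_fi_to_dementia = direct_fi_to_dementia

    def _design(self, age, female, from_state, to_state, from_levels):
        age_c = (np.asarray(age, dtype=float) - 75.0) / 10.0
        female = np.asarray(female, dtype=float)
        cols = {"const": np.ones_like(age_c), "age_c": age_c, "female": female,
                "age_c:female": age_c * female}
        if to_state in CIND_STATES:
            cols["age_c2"] = age_c**2
            cols["age_c2:female"] = age_c**2 * female
        fs = np.asarray(from_state)
        for lv in from_levels[1:]:
            cols[f"from_{lv}"] = (fs == lv).astype(float)
        return pd.DataFrame(cols)

    def fit(self, pairs: pd.DataFrame):
        self.destinations_ = sorted(pairs["to_state"].unique())
        self.models_ = {}
        self._from_levels = {}
        for j in self.destinations_:
            sub = pairs[[allowed_transition(f, j, self.cind_recovery,
                                            self.direct_fi_to_dementia)
                         and f != j for f in pairs["from_state"]]]
            if len(sub) == 0 or (sub["to_state"] == j).sum() == 0:
                warnings.warn(f"no observed transitions into state {j}; probability 0")
                continue
            from_levels = sorted(sub["from_state"].unique())
            X = self._design(sub["age_mid"], sub["female"], sub["from_state"], j,
                             from_levels)
            y = (sub["to_state"] == j).astype(float).to_numpy()
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                if not np.all(np.isfinite(res.bse)):
                    raise ValueError("infinite standard errors")
            except Exception:
                # separation fallback: weakly penalised fit
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-4, L1_wt=0.0)
            self.models_[j] = dict(coef=pd.Series(res.params, index=X.columns),
                                   cov=(pd.DataFrame(res.cov_params(),
                                                     index=X.columns, columns=X.columns)
                                        if hasattr(res, "cov_params") and
                                        np.all(np.isfinite(np.asarray(res.params)))
                                        else None))
            self._from_levels[j] = from_levels
        return self

    def margins(self, coef_override: dict | None = None) -> TwoYearTPTable:
        """Two-year probabilities per (sex, single age, from-state).

        Within each from-state row the destination probabilities plus the
        residual stay probability are renormalised to sum to exactly one.
        """
        rows = []
        grid_age = np.repeat(AGES.astype(float), 2)
        grid_female = np.tile([0.0, 1.0], len(AGES))
        for f in range(1, N_ALIVE + 1):
            probs = {}
            for j, model in self.models_.items():
                if j == f or not allowed_transition(f, j, self.cind_recovery,
                                                    self.direct_fi_to_dementia):
                    continue
                if f not in self._from_levels[j]:
                    continue  # never observed at risk; leave zero
                coef = (coef_override or {}).get(j, model["coef"])
                X = self._design(grid_age, grid_female, np.full_like(grid_age, f),
                                 j, self._from_levels[j])
                probs[j] = expit(X[coef.index].to_numpy() @ coef.to_numpy())
            total = np.sum(list(probs.values()), axis=0) if probs else np.zeros_like(grid_age)
            over = total > 1.0
            scale = np.where(over, 1.0 / np.where(total > 0, total, 1.0), 1.0)
            if over.any():
                warnings.warn(f"renormalising {int(over.sum())} transition rows "
                              f"from state {f} whose destinations exceeded 1")
            for j, p in probs.items():
                rows.append(pd.DataFrame({
                    "sex": np.where(grid_female > 0, "f", "m"),
                    "age": grid_age.astype(int), "from_state": f, "to_state": j,
                    "P": p * scale}))
        if rows:
            margins = pd.concat(rows, ignore_index=True)
        else:
            margins = pd.DataFrame(columns=["sex", "age", "from_state",
                                            "to_state", "P"])
        return TwoYearTPTable(margins=margins, models=self.models_)


def estimate_transition_probabilities(state_panel: pd.DataFrame,
                                      **kwargs) -> TwoYearTPTable:
    pairs = build_transition_pairs(state_panel)
    return TransitionModel(**kwargs).fit(pairs).margins()


def two_year_to_one_year(P):
    """Convert a two-year transition probability to one year:
    TP = 1 - exp(ln(1-P)/2); P=1 maps to 1 by continuity."""
    P = check_prob(P, "two-year probability")
    with np.errstate(divide="ignore"):
        out = 1.0 - np.exp(np.log1p(-P) / 2.0)
    return np.where(P >= 1.0, 1.0, out) if np.ndim(P) else (1.0 if P >= 1.0 else float(out))


# ---------------------------------------------------------------------------
# starting prevalence
# ---------------------------------------------------------------------------

def fit_starting_prevalence(state_panel: pd.DataFrame,
                            taper_power: float = 2.0) -> pd.DataFrame:
    """Smoothed state prevalence by single year of age and sex at the 2006
    anchor, from pooled person-wave states.

    Multinomial logistic in age and age-squared per sex over the observed age
    range; below the observed minimum age the disease-state prevalences taper
    smoothly to zero at age 35 (mass reassigned to the healthy state).
    Every (age, sex) cell sums to one.
    """
    rows = []
    for sex in SEXES:
        sub = state_panel[state_panel["sex"] == sex]
        age_c = (sub["age"].to_numpy() - 75.0) / 10.0
        X = pd.DataFrame({"const": 1.0, "age_c": age_c, "age_c2": age_c**2})
        lo = max(50.0, float(sub["age"].min()))
        ga = (AGES.astype(float) - 75.0) / 10.0
        Xg = np.column_stack([np.ones_like(ga), ga, ga**2])
        # one-vs-rest logistic smooths per state, renormalised across states
        # (a robust replacement for ad-hoc curve fitting of raw prevalences)
        prev = np.zeros((len(AGES), N_ALIVE))
        for s in sorted(sub["state"].unique()):
            ys = (sub["state"] == s).astype(float).to_numpy()
            fit = sm.GLM(ys, X, family=sm.families.Binomial()).fit()
            prev[:, s - 1] = expit(Xg @ fit.params.to_numpy())
        prev /= prev.sum(axis=1, keepdims=True)
        # taper disease prevalence below the observed range
        young = AGES < lo
        tau = ((AGES[young] - 35.0) / (lo - 35.0)) ** taper_power
        ref = prev[AGES.searchsorted(lo)]
        prev[young, :] = ref[None, :] * tau[:, None]
        prev[young, 0] = 1.0 - prev[young, 1:].sum(axis=1)
        total = prev.sum(axis=1)
        if not np.allclose(total, 1.0, atol=1e-8):
            warnings.warn("renormalising starting prevalences")
        prev /= total[:, None]
        for i, a in enumerate(AGES):
            for s in range(1, N_ALIVE + 1):
                rows.append((sex, int(a), s, prev[i, s - 1]))
    return pd.DataFrame(rows, columns=["sex", "age", "state", "prevalence"])


# ---------------------------------------------------------------------------
# state-specific mortality
# ---------------------------------------------------------------------------

@dataclass
class StateMortalityOdds:
    """Odds ratios of two-year death per state (reference: healthy state 1)."""

    log_or: pd.DataFrame  # index state 1..8, columns cvd/noncvd
    cov: dict  # cause -> coefficient covariance (for PSA draws)
    unstable_states: list = field(default_factory=list)

    def odds_ratios(self) -> pd.DataFrame:
        return np.exp(self.log_or)


def estimate_state_mortality_odds(pairs: pd.DataFrame) -> StateMortalityOdds:
    """Per-cause logistic models of two-year death on age, sex and state."""
    out = {}
    covs = {}
    unstable = []
    for cause, code in (("cvd", DEATH_CVD), ("noncvd", DEATH_NONCVD)):
        y = (pairs["to_state"] == code).astype(float)
        age_c = (pairs["age_mid"] - 75.0) / 10.0
        cols = {"const": 1.0, "age_c": age_c, "age_c2": age_c**2,
                "female": pairs["female"]}
        lor = np.zeros(N_ALIVE)
        present = []
        for s in range(2, N_ALIVE + 1):
            has_deaths = ((pairs["from_state"] == s) & (y > 0)).any()
            if has_deaths:
                cols[f"state_{s}"] = (pairs["from_state"] == s).astype(float)
                present.append(s)
            else:
                unstable.append((cause, s))
        X = pd.DataFrame(cols)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for s in present:
            lor[s - 1] = res.params[f"state_{s}"]
        impaired = [s for s in present if s >= 3]
        pooled = np.mean([res.params[f"state_{s}"] for s in impaired]) if impaired else 0.0
        for cause_s, s in [u for u in unstable if u[0] == cause]:
            lor[s - 1] = pooled  # fallback: pooled impaired-state log-OR
        out[cause] = lor
        covs[cause] = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    log_or = pd.DataFrame(out, index=pd.RangeIndex(1, N_ALIVE + 1, name="state"))
    if unstable:
        warnings.warn(f"states with no observed deaths, pooled fallback: {unstable}")
    return StateMortalityOdds(log_or=log_or, cov=covs, unstable_states=unstable)


# ---------------------------------------------------------------------------
# mortality projection
# ---------------------------------------------------------------------------

def project_mortality(series: pd.DataFrame, horizon_year: int = 2040) -> pd.DataFrame:
    """Per-stratum log-linear extrapolation of death rates.

    ``series`` is tidy (year, sex, age_band, cause, value).  Requires at
    least ten years of history per stratum; zero rates are floored at the
    smallest positive rate in the stratum with a warning.  Returns the same
    tidy layout covering every year to ``horizon_year``.
    """
    out = []
    for (sex, band, cause), grp in series.groupby(["sex", "age_band", "cause"]):
        grp = grp.sort_values("year")
        if grp["year"].nunique() < 10:
            raise ValueError(f"need >=10 years of history for {sex}/{band}/{cause}")
        vals = grp["value"].to_numpy(dtype=float)
        if (vals <= 0).any():
            floor = vals[vals > 0].min() if (vals > 0).any() else 1e-8
            warnings.warn(f"flooring non-positive rates in {sex}/{band}/{cause}")
            vals = np.maximum(vals, floor)
        yrs = grp["year"].to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(yrs), yrs - BASE_YEAR])
        coef, *_ = np.linalg.lstsq(A, np.log(vals), rcond=None)
        future = np.arange(int(grp["year"].min()), horizon_year + 1)
        pred = np.exp(coef[0] + coef[1] * (future - BASE_YEAR))
        out.append(pd.DataFrame({"year": future, "sex": sex, "age_band": band,
                                 "cause": cause, "value": pred}))
    return pd.concat(out, ignore_index=True)


def rates_to_single_age(surface: pd.DataFrame) -> dict:
    """Interpolate 5-year-band rates to single year of age by a monotone
    (PCHIP) spline on the log rate.  Returns {(year, sex, cause): array}."""
    mids = np.array([min(0.5 * (lo + hi), 102.0) for lo, hi in AGE_BANDS])
    order = {band_label(lo, hi): i for i, (lo, hi) in enumerate(AGE_BANDS)}
    out = {}
    for (year, sex, cause), grp in surface.groupby(["year", "sex", "cause"]):
        vals = np.empty(len(AGE_BANDS))
        vals[:] = np.nan
        for band, v in zip(grp["age_band"], grp["value"]):
            vals[order[band]] = v
        if np.isnan(vals).any():
            raise ValueError(f"incomplete age bands for {year}/{sex}/{cause}")
        interp = PchipInterpolator(mids, np.log(np.maximum(vals, 1e-12)),
                                   extrapolate=True)
        out[(int(year), sex, cause)] = np.exp(interp(AGES.astype(float)))
    return out


# ---------------------------------------------------------------------------
# scenario specification and transition-set assembly
# ---------------------------------------------------------------------------

SCENARIO_TREND_OR = {"decline-2pct": 0.98, "decline-1.1pct": 0.989, "none": 1.0}


@dataclass
class ScenarioSpec:
    """Which calendar trends to impose on the 2006 transition probabilities."""

    incidence_trend: str | float = "estimated"  # estimated | decline-2pct | decline-1.1pct | none | OR value
    cvd_freeze_year: int | None = None
    horizon_year: int = 2040
    standard_population_year: int = 2015
    name: str = ""

    def __post_init__(self):
        if self.horizon_year < BASE_YEAR:
            raise ValueError("horizon must not precede the 2006 base year")
        if isinstance(self.incidence_trend, str) and self.incidence_trend not in (
                {"estimated"} | set(SCENARIO_TREND_OR)):
            raise ValueError(
                f"unknown incidence_trend {self.incidence_trend!r}; valid: "
                f"'estimated', {sorted(SCENARIO_TREND_OR)} or a numeric OR")
        if not self.name:
            self.name = (self.incidence_trend if isinstance(self.incidence_trend, str)
                         else f"or-{self.incidence_trend}")

    def trend_or(self, estimated: TrendEstimate | float | None = None) -> float:
        if isinstance(self.incidence_trend, (int, float)):
            return float(self.incidence_trend)
        if self.incidence_trend == "estimated":
            if estimated is None:
                raise ValueError("scenario 'estimated' needs a trend estimate")
            return float(getattr(estimated, "odds_ratio_per_year", estimated))
        return SCENARIO_TREND_OR[self.incidence_trend]


@dataclass
class TransitionProbabilitySet:
    """year -> (n_ages, sex, from_state 1..8, to_state 1..10) one-year
    probabilities; every row sums to exactly one."""

    probabilities: dict
    scenario: ScenarioSpec
    metadata: dict = field(default_factory=dict)

    def years(self):
        return sorted(self.probabilities)

    def __getitem__(self, year: int) -> np.ndarray:
        return self.probabilities[int(year)]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for year, arr in sorted(self.probabilities.items()):
            nz = np.argwhere(arr > 0)
            rows.append(pd.DataFrame({
                "year": year,
                "age": AGES[nz[:, 0]],
                "sex": np.where(nz[:, 1] > 0, "f", "m"),
                "from_state": nz[:, 2] + 1,
                "to_state": nz[:, 3] + 1,
                "probability": arr[nz[:, 0], nz[:, 1], nz[:, 2], nz[:, 3]],
            }))
        return pd.concat(rows, ignore_index=True)


def _scale_odds(p: np.ndarray, factor) -> np.ndarray:
    """Multiply the odds of probabilities by a factor (vectorised)."""
    odds = p / (1.0 - np.clip(p, 0.0, 1.0 - 1e-12))
    odds = odds * factor
    return odds / (1.0 + odds)


def cvd_mortality_index(surface_single: dict, years) -> dict:
    """Age-standardised CVD mortality per (sex, year), normalised to 2006 --
    the multiplier applied to CVD-incidence odds (assumption: CVD incidence
    declines in parallel with CVD mortality)."""
    weights = np.exp(-0.5 * ((AGES - 70.0) / 15.0) ** 2)  # broad standard weights
    weights = weights / weights.sum()
    out = {}
    for sex in SEXES:
        base = float(weights @ surface_single[(BASE_YEAR, sex, "cvd")])
        for y in years:
            out[(sex, int(y))] = float(weights @ surface_single[(int(y), sex, "cvd")]) / base
    return out


def build_transition_set(
    tps2006: TwoYearTPTable,
    trend: TrendEstimate | float,
    mortality_surface: pd.DataFrame,
    state_odds: StateMortalityOdds,
    scenario: ScenarioSpec,
    state_weights: pd.DataFrame | None = None,
) -> TransitionProbabilitySet:
    """Assemble calendar-specific one-year transition probabilities.

    For each year to the horizon: dementia- and CIND-incidence entries are
    scaled on the odds scale by the scenario's per-year OR; CVD-incidence
    entries follow the annual change in projected CVD mortality (held
    constant after the freeze year when set); per-state death probabilities
    are the state odds ratios applied to that year's projected cause-specific
    population rates, anchored so the state-weighted mean matches the
    population rate; rows are closed by the residual stay probability.

    ``state_weights``: starting-prevalence table used as the anchoring
    weights (defaults to uniform over alive states).
    """
    or_year = scenario.trend_or(trend)
    years = list(range(BASE_YEAR, scenario.horizon_year + 1))
    single = rates_to_single_age(mortality_surface)
    cvd_idx = cvd_mortality_index(single, years)

    # one-year alive-to-alive base matrix at 2006
    two = tps2006.matrix()  # (ages, sex, 8, 10)
    base = two_year_to_one_year(two[..., :N_ALIVE])

    # anchoring weights over alive states per (age, sex)
    W = np.full((len(AGES), 2, N_ALIVE), 1.0 / N_ALIVE)
    if state_weights is not None:
        for r in state_weights.itertuples(index=False):
            W[int(r.age) - AGES[0], 0 if r.sex == "m" else 1, int(r.state) - 1] = r.prevalence
        W = W / W.sum(axis=2, keepdims=True)

    lor = state_odds.log_or.to_numpy()  # (8, 2) columns cvd, noncvd
    cause_cols = list(state_odds.log_or.columns)

    probs = {}
    clipped = 0
    for y in years:
        arr = np.zeros((len(AGES), 2, N_ALIVE, N_ALIVE + 2))
        alive = base.copy()
        # calendar scaling on the odds scale
        inc_factor = or_year ** (y - BASE_YEAR)
        cvd_y = y if scenario.cvd_freeze_year is None else min(y, scenario.cvd_freeze_year)
        for f in range(N_ALIVE):
            for j in range(N_ALIVE):
                if f == j or not np.any(alive[:, :, f, j] > 0):
                    continue
                factor = np.ones((len(AGES), 2))
                to_dem = (j + 1) in DEMENTIA_STATES and (f + 1) not in DEMENTIA_STATES
                to_cind = (j + 1) in CIND_STATES and (f + 1) not in CIND_STATES
                if to_dem or to_cind:
                    factor *= inc_factor
                if (j + 1) in CVD_STATES and (f + 1) not in CVD_STATES:
                    for si, sex in enumerate(SEXES):
                        factor[:, si] *= cvd_idx[(sex, cvd_y)]
                if not np.all(factor == 1.0):
                    alive[:, :, f, j] = _scale_odds(base[:, :, f, j], factor)
        arr[..., :N_ALIVE] = alive

        # per-state death probabilities anchored to projected population rates
        for ci, cause in enumerate(cause_cols):
            for si, sex in enumerate(SEXES):
                rate = single[(y, sex, cause)]
                q_pop = 1.0 - np.exp(-rate)  # annual probability
                x = slogit(np.clip(q_pop, 1e-12, 1 - 1e-9))
                for _ in range(30):  # Newton: match state-weighted mean
                    p_s = expit(x[:, None] + lor[None, :, ci])
                    mean = (W[:, si, :] * p_s).sum(axis=1)
                    grad = (W[:, si, :] * p_s * (1 - p_s)).sum(axis=1)
                    x = x - (mean - q_pop) / np.maximum(grad, 1e-12)
                p_s = expit(x[:, None] + lor[None, :, ci])
                arr[:, si, :, N_ALIVE + ci] = p_s

        # close rows with the stay probability (diagonals are zero here)
        off = arr.sum(axis=3)
        stay = 1.0 - off
        if (stay < -1e-9).any():
            raise ValueError(f"negative stay probability in year {y}: row exceeds 1")
        neg = stay < 0
        clipped += int(neg.sum())
        stay = np.clip(stay, 0.0, 1.0)
        for s in range(N_ALIVE):
            arr[:, :, s, s] = stay[:, :, s]
        probs[y] = arr
    if clipped:
        warnings.warn(f"clipped {clipped} marginally negative stay probabilities")
    meta = dict(scenario=scenario.name, trend_or=or_year,
                cvd_freeze_year=scenario.cvd_freeze_year,
                horizon_year=scenario.horizon_year)
    return TransitionProbabilitySet(probabilities=probs, scenario=scenario, metadata=meta)
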