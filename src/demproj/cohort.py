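"""Synthetic ageing-panel generator.

Emulates a six-wave biennial panel of adults aged 50+ (2002-2012, with an
auxiliary seventh wave in 2014 used only to resolve transient impairments),
with refreshment recruitment, a latent one-dimensional cognitive trajectory
per person (random intercept and slope), noisy domain test scores, ADL
impairment counts, informant (IQCODE) proxy assessments, doctor-diagnosis
flags, cardiovascular disease, cause-specific mortality with elevated odds
in impaired states, and panel dropout whose hazard depends on the latent
rate of cognitive decline (informative attrition).

Ground truth (latent trajectories, true onset dates, vital histories) is
emitted alongside the observed panel so downstream estimators can be
validated against known parameters.

Also provides generators for ONS-style mortality rate series (log-linear
secular decline on a Gompertz age gradient) and an age-sex population grid
with annual entry cohorts of 35-year-olds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import invlogit, logit, rng_for

BASE_YEAR = 2006  # calendar anchor: generation measures calendar time as year - 2006

WAVE_YEARS = (2002, 2004, 2006, 2008, 2010, 2012)
AUX_WAVE_YEAR = 2014  # wave 7, transience resolution only
NUMERACY_WAVES = (1, 4, 6)
LITERACY_WAVES = (6,)

DOMAIN_TESTS = (
    "orientation",
    "immediate_recall",
    "delayed_recall",
    "fluency",
    "numeracy",
    "literacy",
)

EDUCATION_LEVELS = ("none", "intermediate", "higher")


@dataclass
class TrajectoryParams:
    """Fixed effects and random-effect covariance of the latent cognition model.

    The latent score is in units of the reference-population SD. ``age`` terms
    use centred entry age (age-65)/10; ``time`` is years since study entry.
    """

    intercept: float = 0.25
    age: float = -0.32
    age2: float = -0.15
    time: float = -0.005
    time2: float = 0.0
    female: float = 0.04
    calendar: float = 0.005  # per year, cognition of later cohorts slightly better
    education: tuple[float, float, float] = (0.0, 0.35, 0.65)
    obesity: float = -0.05
    hypertension: float = -0.05
    diabetes: float = -0.15
    sd_intercept: float = 0.50
    sd_slope: float = 0.045
    corr: float = -0.25
    # dementia steepens decline: extra latent drop per year after true onset.
    # Applies to the observed (effective) trajectory only; the pre-onset
    # process that drives onset risk remains linear in time.
    post_onset_decline: float = 0.45

    def re_cov(self) -> np.ndarray:
        c = self.corr * self.sd_intercept * self.sd_slope
        return np.array([[self.sd_intercept**2, c], [c, self.sd_slope**2]])


@dataclass
class EventParams:
    """Two-year discrete-time dementia onset model (ground truth).

    Log-odds are linear in attained age, sex, calendar year, current and
    time-varying risk factors, and the latent cognitive state: the current
    value (``alpha_value``) and slope (``alpha_slope``) of the trajectory.
    Onset can only occur once the latent trajectory is below ``threshold``.
    """

    intercept: float = -2.20  # at age 80, latent 0 (calibrated to observed incidence)
    age: float = 0.10  # per year of attained age, centred at 80
    age2: float = -0.0020
    female: float = 0.44
    alpha_value: float = -0.4
    alpha_slope: float = -4.0
    smoking: float = 0.25
    inactivity: float = 0.32
    hypertension: float = 0.22
    threshold: float = 0.75


@dataclass
class MortalityLink:
    """Log-odds increments of two-year death probabilities by latent state."""

    cvd_on_cvd: float = 1.0
    dementia_on_cvd: float = 1.2
    impaired_on_cvd: float = 0.3
    cvd_on_noncvd: float = 0.25
    dementia_on_noncvd: float = 2.2
    impaired_on_noncvd: float = 0.35


@dataclass
class CohortConfig:
    """Study-design configuration for the synthetic panel."""

    n_core: int = 9600
    # (wave index, calendar year, (age lo, age hi), n)
    recruitment_waves: tuple = (
        (3, 2006, (50, 55), 1200),
        (4, 2008, (50, 74), 2700),
        (6, 2012, (50, 55), 1500),
    )
    wave_years: tuple = WAVE_YEARS
    include_aux_wave: bool = True
    true_incidence_trend_or: float = 0.973  # total per-year odds ratio, direct + risk-factor mediated
    dropout_params: tuple[float, float] = (0.11, 0.7)  # (baseline per-epoch prob, log-odds per SD decline)
    risk_factor_prevalences: dict = field(
        default_factory=lambda: {
            "education": (0.32, 0.45, 0.23),
            "midlife_obesity": 0.22,
            "midlife_hypertension": 0.30,
            "midlife_diabetes": 0.06,
            "smoking": 0.24,
            "inactivity_logit": -0.65,
            "hypertension_logit": -0.80,
        }
    )
    # per-year improvement of time-varying risk factors (logit scale for the
    # two propensity-driven factors; per-epoch quit probability for smoking)
    rf_trends: dict = field(
        default_factory=lambda: {
            "smoking_quit_per_epoch": 0.15,
            "inactivity_logit_per_year": -0.068,
            "hypertension_logit_per_year": -0.045,
        }
    )
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)
    event_params: EventParams = field(default_factory=EventParams)
    mortality_link: MortalityLink = field(default_factory=MortalityLink)
    # two-year death models: logit intercept at age 77 / slope per year / male shift / per-year trend
    mortality_params: dict = field(
        default_factory=lambda: {
            "cvd": {"intercept": -4.35, "age": 0.092, "male": 0.28,
                    "trend_male": -0.042, "trend_female": -0.036},
            "noncvd": {"intercept": -3.05, "age": 0.094, "male": 0.18,
                       "trend_male": -0.012, "trend_female": -0.010},
        }
    )
    measurement_sd: dict = field(
        default_factory=lambda: {
            "orientation": 0.45,
            "immediate_recall": 0.40,
            "delayed_recall": 0.40,
            "fluency": 0.40,
            "numeracy": 0.45,
            "literacy": 0.50,
        }
    )
    # share of the analytically computed risk-factor mediation that is
    # realised in the simulated population (cohort turnover, ageing and
    # event-pool composition damp the plug-in formula; calibrated once by
    # simulation with the latent coupling switched off)
    mediation_realization: float = 0.6
    prop_female: float = 0.54
    seed: int | None = None

    def __post_init__(self):
        if self.seed is not None and (int(self.seed) != self.seed):
            raise ValueError("seed must be an integer")
        if self.n_core <= 0:
            raise ValueError("n_core must be positive")
        for w, yr, rng_, n in self.recruitment_waves:
            if n <= 0:
                raise ValueError("recruitment n must be positive")
            if not (1 <= w <= len(self.wave_years)):
                raise ValueError("recruitment wave outside the panel")
        years = list(self.wave_years)
        if any(b - a != 2 for a, b in zip(years, years[1:])):
            raise ValueError("wave_years must be strictly increasing with spacing 2")
        if self.true_incidence_trend_or <= 0:
            raise ValueError("true_incidence_trend_or must be > 0")
        p0, _ = self.dropout_params
        if not 0.0 <= p0 <= 1.0:
            raise ValueError("baseline dropout probability must be in [0, 1]")

    # The configured trend OR is the *total* per-year trend. Part of it is
    # mediated by secular improvement in the time-varying risk factors; the
    # remainder enters the event model directly as a calendar coefficient.
    def mediated_trend(self) -> float:
        rf = self.risk_factor_prevalences
        tr = self.rf_trends
        ev = self.event_params
        p_sm = rf["smoking"]
        d_sm = -tr["smoking_quit_per_epoch"] / 2.0 * p_sm
        p_pa = invlogit(rf["inactivity_logit"])
        d_pa = tr["inactivity_logit_per_year"] * p_pa * (1 - p_pa)
        p_ht = invlogit(rf["hypertension_logit"])
        d_ht = tr["hypertension_logit_per_year"] * p_ht * (1 - p_ht)
        return ev.smoking * d_sm + ev.inactivity * d_pa + ev.hypertension * d_ht

    def direct_trend_logodds(self) -> float:
        return (math.log(self.true_incidence_trend_or)
                - self.mediation_realization * self.mediated_trend())


@dataclass
class PanelDataset:
    """Observed panel plus ground-truth sidecars."""

    panel: pd.DataFrame
    truth_persons: pd.DataFrame
    truth_panel: pd.DataFrame
    config: CohortConfig

    def to_csv(self, panel_path, truth_persons_path=None, truth_panel_path=None):
        self.panel.to_csv(panel_path, index=False)
        if truth_persons_path:
            self.truth_persons.to_csv(truth_persons_path, index=False)
        if truth_panel_path:
            self.truth_panel.to_csv(truth_panel_path, index=False)


def _sample_entry_ages(rng, n, lo, hi):
    ages = np.arange(lo, hi + 1)
    w = np.exp(-0.055 * (ages - 50.0))
    w /= w.sum()
    return rng.choice(ages, size=n, p=w) + rng.random(n)  # continuous age at entry


def generate_cohort(config: CohortConfig) -> PanelDataset:
    """Simulate the panel under the configured ground truth.

    Returns the observed person-wave panel and two truth sidecars (one row
    per person; one row per person-wave with the latent state).
    """
    if config.seed is None:
        raise ValueError("config.seed is required")
    cfg = config
    tp = cfg.trajectory_params
    ev = cfg.event_params
    ml = cfg.mortality_link
    rng = rng_for(cfg.seed, 0)

    wave_years = list(cfg.wave_years)
    n_waves = len(wave_years)
    all_waves = list(range(1, n_waves + 1))
    aux_wave = n_waves + 1 if cfg.include_aux_wave else None

    # ---- assemble persons -------------------------------------------------
    entry_wave = [np.full(cfg.n_core, 1)]
    entry_age = [_sample_entry_ages(rng, cfg.n_core, 50, 90)]
    for w, yr, (lo, hi), n in cfg.recruitment_waves:
        entry_wave.append(np.full(n, w))
        entry_age.append(_sample_entry_ages(rng, n, lo, hi))
    entry_wave = np.concatenate(entry_wave)
    entry_age = np.concatenate(entry_age)
    N = entry_wave.size
    pid = np.arange(N)
    entry_year = np.array([wave_years[w - 1] for w in entry_wave])

    female = rng.random(N) < cfg.prop_female
    rfp = cfg.risk_factor_prevalences
    educ_idx = rng.choice(3, size=N, p=np.asarray(rfp["education"], dtype=float))
    ob = rng.random(N) < rfp["midlife_obesity"]
    ht_mid = rng.random(N) < rfp["midlife_hypertension"]
    db = rng.random(N) < rfp["midlife_diabetes"]
    p_smoke0 = np.clip(rfp["smoking"] - 0.005 * (entry_year - 2002), 0.02, 1.0)
    smoking = rng.random(N) < p_smoke0
    zeta_pa = rng.normal(0, 1.3, N)  # inactivity propensity
    xi_ht = rng.normal(0, 1.3, N)  # current-hypertension propensity
    u_adl = rng.normal(0, 0.9, N)  # persistent frailty for ADL reporting

    L = np.linalg.cholesky(tp.re_cov())
    b = rng.standard_normal((N, 2)) @ L.T
    b0, b1 = b[:, 0], b[:, 1]

    educ_eff = np.asarray(tp.education)[educ_idx]
    person_shift = (
        tp.intercept
        + tp.female * female
        + educ_eff
        + tp.obesity * ob
        + tp.hypertension * ht_mid
        + tp.diabetes * db
    )

    def _yc(year):
        """Calendar covariate, clamped 20 years either side of the anchor so
        pre-entry back-extrapolation stays in a plausible range."""
        return np.clip(np.asarray(year, dtype=float) - BASE_YEAR, -20.0, 40.0)

    # The age profile is a function of *attained* age, so that (conditional
    # on the person-level shifts) cross-sections at a given age are
    # stationary: people long in the study and recent entrants of the same
    # age share the same mean trajectory, differing only through their
    # mean-zero random intercept and slope.
    def _age_profile(attained_age):
        a = (attained_age - 65.0) / 10.0
        return tp.age * a + tp.age2 * a**2

    def latent(t, year):
        """Latent cognition at time-since-entry t (years), calendar `year`."""
        return (
            person_shift
            + _age_profile(entry_age + t)
            + tp.time * t
            + tp.time2 * t**2
            + tp.calendar * _yc(year)
            + b0
            + b1 * t
        )

    def latent_slope(t):
        a = (entry_age + t - 65.0) / 10.0
        return (tp.age + 2.0 * tp.age2 * a) / 10.0 + tp.time + 2.0 * tp.time2 * t + b1

    def latent_effective(t, year):
        """Observed latent state: pre-onset trajectory plus post-onset decline."""
        since = np.maximum(0.0, year - np.where(np.isnan(onset_year), np.inf, onset_year))
        return latent(t, year) - tp.post_onset_decline * since

    trend_direct = cfg.direct_trend_logodds()
    mp = cfg.mortality_params
    tr = cfg.rf_trends

    def onset_logodds(age_mid, female_, year_mid, c_mid, slope, smoke, inact, htn):
        return (
            ev.intercept
            + ev.age * (age_mid - 80.0)
            + ev.age2 * (age_mid - 80.0) ** 2
            + ev.female * female_
            + trend_direct * _yc(year_mid)
            + ev.alpha_value * c_mid
            + ev.alpha_slope * slope
            + ev.smoking * smoke
            + ev.inactivity * inact
            + ev.hypertension * htn
        )

    def death_probs(age_mid, male, year_mid, cvd_, dem_, impaired):
        trend_cvd = np.where(male, mp["cvd"]["trend_male"], mp["cvd"]["trend_female"])
        trend_ncvd = np.where(male, mp["noncvd"]["trend_male"], mp["noncvd"]["trend_female"])
        q_cvd = invlogit(
            mp["cvd"]["intercept"] + mp["cvd"]["age"] * (age_mid - 77.0)
            + mp["cvd"]["male"] * male + trend_cvd * _yc(year_mid)
            + ml.cvd_on_cvd * cvd_ + ml.dementia_on_cvd * dem_
            + ml.impaired_on_cvd * impaired
        )
        q_ncvd = invlogit(
            mp["noncvd"]["intercept"] + mp["noncvd"]["age"] * (age_mid - 77.0)
            + mp["noncvd"]["male"] * male + trend_ncvd * _yc(year_mid)
            + ml.cvd_on_noncvd * cvd_ + ml.dementia_on_noncvd * dem_
            + ml.impaired_on_noncvd * impaired
        )
        return q_cvd, q_ncvd, trend_cvd

    # ---- entry-state equilibration ---------------------------------------
    # The pre-entry disease/mortality history of every recruit is simulated
    # with the same models in two-year steps from age ~50, redrawing the
    # latent path of candidates who die before recruitment (a cross-section
    # of survivors, which keeps the entry state at the model's own
    # equilibrium rather than leaving an excess stock of near-onset people).
    onset_year = np.full(N, np.nan)
    dem = np.zeros(N, bool)
    cvd = rng.random(N) < invlogit(-2.6 + 0.05 * (entry_age - 62.0) + 0.5 * (~female))
    n_pre = np.maximum(0, np.floor((entry_age - 50.0) / 2.0)).astype(int)
    max_pre = int(n_pre.max()) if N else 0
    pending = np.ones(N, bool)

    def _simulate_pre(active: np.ndarray, allow_death: bool) -> np.ndarray:
        """One pre-entry pass for `active` persons; returns died-before-entry."""
        died_pre = np.zeros(N, bool)
        for s in range(max_pre, 0, -1):
            sub = np.where(active & (n_pre >= s) & ~died_pre)[0]
            if sub.size == 0:
                continue
            t_mid = -2.0 * s + 1.0
            year_mid = entry_year[sub] + t_mid
            age_mid = entry_age[sub] + t_mid
            c_mid = (person_shift[sub] + _age_profile(age_mid)
                     + tp.time * t_mid + tp.time2 * t_mid**2
                     + tp.calendar * _yc(year_mid) + b0[sub] + b1[sub] * t_mid)
            since = np.maximum(0.0, year_mid - np.where(np.isnan(onset_year[sub]), np.inf,
                                                        onset_year[sub]))
            c_eff = c_mid - tp.post_onset_decline * since
            slope = ((tp.age + 2.0 * tp.age2 * (age_mid - 65.0) / 10.0) / 10.0
                     + tp.time + 2.0 * tp.time2 * t_mid + b1[sub])
            inact = rng.random(sub.size) < invlogit(
                rfp["inactivity_logit"] + zeta_pa[sub] + 0.03 * (age_mid - 65.0)
                + tr["inactivity_logit_per_year"] * np.maximum(year_mid - 2002, -16)
            )
            htn_c = rng.random(sub.size) < invlogit(
                rfp["hypertension_logit"] + xi_ht[sub] + 0.05 * (age_mid - 65.0)
                + tr["hypertension_logit_per_year"] * np.maximum(year_mid - 2002, -16)
            )
            if allow_death:
                q_cvd, q_ncvd, _ = death_probs(age_mid, ~female[sub], year_mid, cvd[sub],
                                               dem[sub], c_eff < -1.0)
                died_pre[sub] |= rng.random(sub.size) < (q_cvd + q_ncvd)
            keep = ~died_pre[sub] & ~dem[sub]
            still = sub[keep]
            if still.size:
                eta = onset_logodds(age_mid[keep], female[still], year_mid[keep],
                                    c_mid[keep], slope[keep], smoking[still],
                                    inact[keep], htn_c[keep])
                p_on = np.where(c_mid[keep] < ev.threshold, invlogit(eta), 0.0)
                hit = rng.random(still.size) < p_on
                dem[still[hit]] = True
                onset_year[still[hit]] = year_mid[keep][hit]
        return died_pre

    for attempt in range(150):
        idx_p = np.where(pending)[0]
        if idx_p.size == 0:
            break
        if attempt > 0:
            nb = rng.standard_normal((idx_p.size, 2)) @ L.T
            b0[idx_p], b1[idx_p] = nb[:, 0], nb[:, 1]
            dem[idx_p] = False
            onset_year[idx_p] = np.nan
        pending = _simulate_pre(pending, allow_death=True)
    if pending.any():
        # a handful of the very oldest recruits have vanishing model survival;
        # accept an unconditioned path for them rather than rejecting forever
        idx_p = np.where(pending)[0]
        nb = rng.standard_normal((idx_p.size, 2)) @ L.T
        b0[idx_p], b1[idx_p] = nb[:, 0], nb[:, 1]
        dem[idx_p] = False
        onset_year[idx_p] = np.nan
        _simulate_pre(pending, allow_death=False)

    alive = np.ones(N, bool)
    dropped = np.zeros(N, bool)
    death_year = np.full(N, np.nan)
    death_cause = np.array([""] * N, dtype=object)
    dropout_after_wave = np.full(N, np.nan)
    dx_reported = np.zeros(N, bool)
    dx_false = np.zeros(N, bool)

    p0_drop, kappa_drop = cfg.dropout_params
    sd_b1 = tp.sd_slope if tp.sd_slope > 0 else 1.0

    panel_rows = []
    truth_rows = []

    # Time-varying risk factors are drawn once per wave for *all* persons
    # (dropouts included) so the onset model and the observed panel share the
    # same covariate path.  Smoking is a persistent state updated per epoch.
    all_wave_years = wave_years + ([AUX_WAVE_YEAR] if aux_wave else [])
    inact_by_wave, htn_by_wave = {}, {}
    for w_, yr_ in enumerate(all_wave_years, start=1):
        age_now = entry_age + (yr_ - entry_year)
        p_inact = invlogit(
            rfp["inactivity_logit"] + zeta_pa + 0.03 * (age_now - 65.0)
            + tr["inactivity_logit_per_year"] * (yr_ - 2002)
        )
        p_htn = invlogit(
            rfp["hypertension_logit"] + xi_ht + 0.05 * (age_now - 65.0)
            + tr["hypertension_logit_per_year"] * (yr_ - 2002)
        )
        inact_by_wave[w_] = rng.random(N) < p_inact
        htn_by_wave[w_] = rng.random(N) < p_htn

    def observe_wave(w, year):
        """Record interview data for everyone under observation at wave w."""
        in_study = alive & ~dropped & (entry_wave <= min(w, n_waves))
        idx = np.where(in_study)[0]
        if idx.size == 0:
            return
        t_full = year - entry_year  # years since entry, full person vector
        t = t_full[idx]
        age_now = entry_age[idx] + t
        c = latent_effective(t_full, year)[idx]
        inact = inact_by_wave[w]
        htn_cur = htn_by_wave[w]

        # interview mode: proxy (informant) interviews for the most impaired
        p_proxy = invlogit(-3.6 - 1.6 * c + 1.2 * dem[idx])
        proxy = rng.random(idx.size) < p_proxy

        msd = cfg.measurement_sd
        scores = {}
        answered = np.zeros(idx.size, dtype=int)
        for test in DOMAIN_TESTS:
            if test == "numeracy" and w not in NUMERACY_WAVES:
                scores[f"score_{test}"] = np.full(idx.size, np.nan)
                continue
            if test == "literacy" and w not in LITERACY_WAVES:
                scores[f"score_{test}"] = np.full(idx.size, np.nan)
                continue
            val = c + {"immediate_recall": 0.1, "delayed_recall": -0.1, "numeracy": 0.05}.get(test, 0.0)
            val = val + rng.normal(0, msd[test], idx.size)
            miss = proxy | (rng.random(idx.size) < 0.02)
            val[miss] = np.nan
            scores[f"score_{test}"] = val
            answered += (~miss).astype(int)

        iqcode = np.full(idx.size, np.nan)
        iq = np.clip(3.15 - 0.45 * c + 0.5 * dem[idx] + rng.normal(0, 0.22, idx.size), 1.0, 5.0)
        iqcode[proxy] = iq[proxy]

        p_adl = invlogit(
            -4.25 + 0.045 * (age_now - 65.0) - 0.4 * np.minimum(c, 0.5)
            + 2.3 * dem[idx] + 0.4 * cvd[idx] + u_adl[idx]
        )
        adl = rng.binomial(7, p_adl)

        # doctor diagnosis: sticky reporting after true onset, rare false positives
        waves_since = np.maximum(0.0, (year - onset_year[idx]) / 2.0)
        p_dx = np.where(dem[idx], np.minimum(0.22 + 0.12 * waves_since, 0.65), 0.0)
        newly = rng.random(idx.size) < p_dx
        dx_reported[idx[newly]] = True
        newly_false = rng.random(idx.size) < 0.0008
        dx_false[idx[newly_false]] = True

        panel_rows.append(
            pd.DataFrame(
                {
                    "person_id": pid[idx],
                    "wave": w,
                    "year": year,
                    "age": age_now,
                    "sex": np.where(female[idx], "f", "m"),
                    "education": np.asarray(EDUCATION_LEVELS)[educ_idx[idx]],
                    **{k: v for k, v in scores.items()},
                    "n_tests_answered": answered,
                    "adl_impaired_count": adl,
                    "iqcode": iqcode,
                    "doctor_dx_dementia": (dx_reported[idx] | dx_false[idx]).astype(int),
                    "cvd_status": cvd[idx].astype(int),
                    "smoking": smoking[idx].astype(int),
                    "inactivity": inact[idx].astype(int),
                    "current_hypertension": htn_cur[idx].astype(int),
                    "midlife_obesity": ob[idx].astype(int),
                    "midlife_hypertension": ht_mid[idx].astype(int),
                    "midlife_diabetes": db[idx].astype(int),
                    "weight": 1.0,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "person_id": pid[idx],
                    "wave": w,
                    "year": year,
                    "latent": latent(t_full, year)[idx],  # pre-onset process
                    "latent_effective": c,
                    "latent_slope": latent_slope(t_full)[idx],
                    "true_dementia": dem[idx].astype(int),
                    "cvd_status": cvd[idx].astype(int),
                }
            )
        )

    def epoch_update(e):
        """Advance disease, death, dropout across the epoch (wave e, wave e+1)."""
        nonlocal dem, cvd, alive, dropped, smoking
        year0 = wave_years[e - 1]
        year_mid = year0 + 1.0
        entered = entry_wave <= e
        at_risk = alive & entered
        idx = np.where(at_risk)[0]
        if idx.size == 0:
            return
        t_mid_full = year_mid - entry_year
        t_mid = t_mid_full[idx]
        age_mid = entry_age[idx] + t_mid
        c_mid = latent(t_mid_full, year_mid)[idx]  # pre-onset process (drives onset risk)
        c_mid_eff = latent_effective(t_mid_full, year_mid)[idx]
        slope = latent_slope(t_mid_full)[idx]
        inact = inact_by_wave[e][idx]  # risk factors at the epoch's starting wave
        htn_cur = htn_by_wave[e][idx]

        # cause-specific deaths (state-linked)
        male = ~female[idx]
        q_cvd, q_ncvd, trend_cvd = death_probs(age_mid, male, year_mid, cvd[idx],
                                               dem[idx], c_mid_eff < -1.0)
        u = rng.random(idx.size)
        die_cvd = u < q_cvd
        die_ncvd = (~die_cvd) & (u < q_cvd + q_ncvd)
        died = die_cvd | die_ncvd
        alive[idx[died]] = False
        death_year[idx[die_cvd]] = year_mid
        death_year[idx[die_ncvd]] = year_mid
        death_cause[idx[die_cvd]] = "cvd"
        death_cause[idx[die_ncvd]] = "noncvd"

        # dementia onset among survivors (continues after dropout)
        surv = idx[~died]
        m = ~dem[surv]
        cand = surv[m]
        if cand.size:
            keep = np.isin(idx, cand)
            eta = onset_logodds(age_mid[keep], female[cand], year_mid, c_mid[keep],
                                slope[keep], smoking[cand], inact[keep], htn_cur[keep])
            p_onset = np.where(c_mid[keep] < ev.threshold, invlogit(eta), 0.0)
            onsets = rng.random(cand.size) < p_onset
            dem[cand[onsets]] = True
            onset_year[cand[onsets]] = year_mid

        # panel dropout among surviving, still-observed participants
        obs = alive[idx] & ~dropped[idx]
        cand_d = idx[obs]
        if cand_d.size:
            eta_d = logit(np.full(cand_d.size, p0_drop)) + kappa_drop * (-b1[cand_d] / sd_b1)
            drops = rng.random(cand_d.size) < invlogit(eta_d)
            dropped[cand_d[drops]] = True
            dropout_after_wave[cand_d[drops]] = e

        # incident cardiovascular disease among survivors (trend tied to CVD mortality)
        cand_c = idx[alive[idx] & ~cvd[idx]]
        if cand_c.size:
            keep = np.isin(idx, cand_c)
            eta_c = (
                -4.6 + 0.055 * (age_mid[keep] - 65.0) + 0.35 * (~female[cand_c])
                + trend_cvd[keep] * (year_mid - BASE_YEAR)
                + 0.35 * smoking[cand_c] + 0.30 * inact[keep] + 0.45 * htn_cur[keep]
                + 0.30 * db[cand_c] + 0.25 * ob[cand_c]
            )
            inc = rng.random(cand_c.size) < invlogit(eta_c)
            cvd[cand_c[inc]] = True

        # smoking cessation
        quitters = smoking & at_risk & (rng.random(N) < cfg.rf_trends["smoking_quit_per_epoch"])
        smoking = smoking & ~quitters

    # ---- main loop: wave observation then epoch update --------------------
    for w in all_waves:
        observe_wave(w, wave_years[w - 1])
        epoch_update(w)
    if aux_wave is not None:
        observe_wave(aux_wave, AUX_WAVE_YEAR)

    panel = pd.concat(panel_rows, ignore_index=True)
    truth_panel = pd.concat(truth_rows, ignore_index=True)

    person_info = pd.DataFrame(
        {
            "person_id": pid,
            "entry_wave": entry_wave,
            "entry_year": entry_year,
            "entry_age": entry_age,
            "sex": np.where(female, "f", "m"),
            "b_intercept": b0,
            "b_slope": b1,
            "true_dementia_ever": dem.astype(int),
            "true_onset_year": onset_year,
            "death_year": death_year,
            "death_cause": np.where(death_cause == "", np.nan, death_cause),
            "dropout_after_wave": dropout_after_wave,
        }
    )

    # person-level vital/dropout columns merged onto the panel for convenience
    panel = panel.merge(
        person_info[["person_id", "entry_wave", "entry_year", "death_year", "death_cause",
                     "dropout_after_wave"]],
        on="person_id",
        how="left",
    )
    panel["vital_status"] = np.where(panel["death_year"].notna(), "dead", "alive")
    panel["dropped_out"] = panel["dropout_after_wave"].notna().astype(int)

    return PanelDataset(panel=panel, truth_persons=person_info, truth_panel=truth_panel, config=cfg)


# ---------------------------------------------------------------------------
# ONS-style mortality series and population grid
# ---------------------------------------------------------------------------

AGE_BANDS = tuple((lo, lo + 4) for lo in range(35, 100, 5)) + ((100, 120),)


def band_label(lo: int, hi: int) -> str:
    return "100+" if lo >= 100 else f"{lo}-{hi}"


@dataclass
class MortalityTrend:
    """Per-year relative decline in death rates, by cause and sex."""

    cvd_male: float = 0.040
    cvd_female: float = 0.035
    noncvd_male: float = 0.012
    noncvd_female: float = 0.010

    def decline(self, cause: str, sex: str) -> float:
        return getattr(self, f"{cause}_{'male' if sex == 'm' else 'female'}")


def generate_mortality_series(
    trend: MortalityTrend | None = None,
    first_year: int = 1996,
    base_year: int = BASE_YEAR,
    horizon: int = 10,
    base_rates: dict | None = None,
) -> pd.DataFrame:
    """Tidy historical mortality-rate series (year, sex, age_band, cause, value).

    Rates (deaths per person-year) follow a Gompertz-like age gradient with a
    log-linear calendar decline per cause and sex, anchored at ``base_year``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    trend = trend or MortalityTrend()
    if base_rates is None:
        base_rates = {}
        for lo, hi in AGE_BANDS:
            mid = min(0.5 * (lo + hi), 102.0)
            base = 1e-3 * 2 ** ((mid - 40.0) / 7.4)  # all-cause, doubling every ~7.4y
            cvd_share = np.clip(0.18 + 0.0025 * (mid - 50.0), 0.1, 0.42)
            for sex, mult in (("m", 1.25), ("f", 0.8)):
                base_rates[(band_label(lo, hi), sex, "cvd")] = base * mult * cvd_share
                base_rates[(band_label(lo, hi), sex, "noncvd")] = base * mult * (1 - cvd_share)
    for v in base_rates.values():
        if v < 0:
            raise ValueError("baseline mortality rates must be non-negative")
    years = np.arange(first_year, base_year + horizon + 1)
    rows = []
    for (band, sex, cause), r0 in base_rates.items():
        d = trend.decline(cause, sex)
        rows.append(
            pd.DataFrame(
                {
                    "year": years,
                    "sex": sex,
                    "age_band": band,
                    "cause": cause,
                    "value": r0 * (1.0 - d) ** (years - base_year),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def default_population_counts(total_35plus: float = 28.0e6) -> pd.DataFrame:
    """Stylised single-year age-sex population counts at the 2006 base year.

    A smooth synthetic age curve (roughly constant cohort sizes to age 60,
    then mortality-thinned), scaled so the 35+ total matches ``total_35plus``.
    """
    ages = np.arange(35, 101)
    # smooth pyramid with a post-war-style cohort bulge around ages 40-60
    bulge = 1.0 + 0.22 * np.exp(-0.5 * ((ages - 46.0) / 8.0) ** 2)
    old = np.exp(-(np.maximum(ages - 60.0, 0.0) / 26.0) ** 2.2)
    shape = np.where(ages <= 60, bulge, old * bulge[ages.searchsorted(60)])
    rows = []
    for sex, frac in (("m", 0.48), ("f", 0.52)):
        s = shape.copy()
        if sex == "f":  # women survive longer
            s[ages > 60] = (np.exp(-((ages[ages > 60] - 60.0) / 29.0) ** 2.2)
                            * bulge[ages.searchsorted(60)])
        counts = s / s.sum()
        rows.append(pd.DataFrame({"year": BASE_YEAR, "sex": sex, "age": ages,
                                  "value": counts * total_35plus * frac}))
    return pd.concat(rows, ignore_index=True)


def generate_population_structure(
    base_counts: pd.DataFrame | None = None,
    entry_series: pd.Series | dict | None = None,
    horizon_year: int = 2040,
) -> pd.DataFrame:
    """Population grid: base-year counts plus entering 35-year-old cohorts.

    ``entry_series`` maps calendar year -> number of people reaching age 35
    (per sex it is split with the base-year sex ratio at age 35).
    Returns tidy rows (year, sex, age, value); future years carry only the
    age-35 entry row, matching the engine's input contract.
    """
    if base_counts is None:
        base_counts = default_population_counts()
    base = base_counts[base_counts["year"] == base_counts["year"].min()]
    ages = np.arange(35, 101)
    for sex in ("m", "f"):
        have = set(base.loc[base["sex"] == sex, "age"].astype(int))
        missing = [a for a in ages if a not in have]
        if missing:
            raise ValueError(f"base year missing age cells for sex={sex}: {missing[:5]}")
    base_year = int(base["year"].iloc[0])
    if entry_series is None:
        yrs = np.arange(base_year + 1, horizon_year + 1)
        entry_series = pd.Series(730e3 + 1.5e3 * (yrs - base_year), index=yrs)
    entry_series = pd.Series(entry_series)
    if (entry_series < 0).any() or (base["value"] < 0).any():
        raise ValueError("population counts must be non-negative")
    at35 = base[base["age"] == 35].set_index("sex")["value"]
    frac_m = float(at35["m"] / at35.sum())
    rows = [base]
    for yr, total in entry_series.items():
        rows.append(pd.DataFrame({"year": int(yr), "sex": ["m", "f"], "age": 35,
                                  "value": [total * frac_m, total * (1 - frac_m)]}))
    return pd.concat(rows, ignore_index=True)
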