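"""State mapping, transition estimation, probability conversion, prevalence
smoothing, state mortality, mortality projection and transition-set rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from demproj.calibration import (DEATH_CVD, DEATH_NONCVD, HealthState,
                                 ScenarioSpec, TransitionModel,
                                 allowed_transition, build_transition_pairs,
                                 build_transition_set, derive_states,
                                 estimate_state_mortality_odds,
                                 fit_starting_prevalence, project_mortality,
                                 two_year_to_one_year)
from demproj.cohort import generate_mortality_series
from demproj.trends import trend_from_coef
from conftest import make_panel


# ---------------------------------------------------------------------- states

def test_state_flags_match_figure_constraints():
    dem = [s for s in range(1, 9) if HealthState(s).has_dementia]
    fi = [s for s in range(1, 9) if HealthState(s).has_functional_impairment]
    assert dem == [6, 7]
    assert fi == [5, 6, 7, 8]
    assert all(HealthState(s).has_functional_impairment for s in dem)


def test_derive_states_mapping():
    panel = make_panel([
        dict(person_id=1, wave=1),                          # healthy
        dict(person_id=2, wave=1, cvd_status=1),            # CVD only
        dict(person_id=3, wave=1),                          # CIND via flags
        dict(person_id=4, wave=1, cvd_status=1),            # dementia + CVD
        dict(person_id=5, wave=1, adl_impaired_count=2),    # FI, no dementia
    ])
    statuses = pd.DataFrame({
        "person_id": [1, 2, 3, 4, 5],
        "is_case": [False, False, False, True, False],
        "onset_year": [np.nan] * 3 + [2001.0, np.nan],
        "prevalent_at_entry": [False, False, False, True, False],
        "ascertainment_wave": [np.nan] * 3 + [1, np.nan],
        "ascertainment_year": [np.nan] * 3 + [2002, np.nan],
        "route": "", "numeracy_dependent": False,
    })
    cog = pd.DataFrame({"person_id": [3], "wave": [1], "cognitive_impairment": [True]})
    fun = pd.DataFrame({"person_id": [5], "wave": [1], "functional_impairment": [True]})
    states = derive_states(panel, statuses, cog, fun).set_index("person_id")["state"]
    assert states.loc[1] == 1 and states.loc[2] == 2
    assert states.loc[3] == 3 and states.loc[4] == 7 and states.loc[5] == 5


def test_transition_rules():
    assert not allowed_transition(6, 1)   # no recovery from dementia
    assert not allowed_transition(2, 1)   # CVD is never lost
    assert allowed_transition(3, 1)       # CIND recovery is real
    assert allowed_transition(5, 6) and allowed_transition(8, 7)
    assert all(allowed_transition(s, DEATH_CVD) for s in range(1, 9))
    assert not allowed_transition(5, 6, direct_fi_to_dementia=False)


def test_death_assignment_in_pairs():
    sp = pd.DataFrame({
        "person_id": [1, 2, 2], "wave": [1, 1, 2], "year": [2002, 2002, 2004],
        "age": [70.0, 70.0, 72.0], "sex": "m", "state": [1, 1, 2],
        "death_year": [2003.0, np.nan, np.nan], "death_cause": ["cvd", np.nan, np.nan],
        "entry_year": 2002,
    })
    pairs = build_transition_pairs(sp)
    assert pairs.set_index("person_id").loc[1, "to_state"] == DEATH_CVD
    assert pairs.set_index("person_id").loc[2, "to_state"] == 2


# ------------------------------------------------------------- TP estimation

def test_no_observed_transitions_gives_zero_probabilities():
    pairs = pd.DataFrame({
        "person_id": range(40), "wave": 1, "year": 2002,
        "age_mid": np.linspace(60, 90, 40), "female": 0.0, "sex": "m",
        "from_state": [1] * 40, "to_state": [1] * 40,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = TransitionModel().fit(pairs).margins()
    assert (table.margins["P"] == 0).all() or table.margins.empty


def test_margin_rows_bounded_and_renormalisable(small_bundle):
    m = small_bundle.tp_table.margins
    assert m["P"].between(0, 1).all()
    sums = m.groupby(["sex", "age", "from_state"])["P"].sum()
    assert (sums <= 1.0 + 1e-9).all()


def test_transition_recovery_from_known_logistic():
    """Pairs simulated from a known destination model are recovered within
    Monte-Carlo tolerance."""
    rng = np.random.default_rng(5)
    n = 20000
    age = rng.uniform(55, 95, n)
    female = rng.integers(0, 2, n).astype(float)
    eta = -3.0 + 0.6 * (age - 75) / 10 + 0.2 * female
    to2 = rng.random(n) < expit(eta)
    pairs = pd.DataFrame({
        "person_id": range(n), "wave": 1, "year": 2002, "age_mid": age,
        "female": female, "sex": np.where(female > 0, "f", "m"),
        "from_state": 1, "to_state": np.where(to2, 2, 1),
    })
    table = TransitionModel().fit(pairs).margins()
    got = table.margins.query("sex=='m' and age==75 and from_state==1 and to_state==2")
    assert abs(float(got["P"].iloc[0]) - expit(-3.0)) < 0.01


# ------------------------------------------------------ probability conversion

def test_two_year_to_one_year_values():
    assert two_year_to_one_year(0.0) == 0.0
    assert np.isclose(two_year_to_one_year(0.19), 0.10, atol=1e-12)
    assert two_year_to_one_year(1.0) == 1.0
    with pytest.raises(ValueError):
        two_year_to_one_year(1.2)


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=0.0, max_value=0.999999))
def test_two_year_one_year_roundtrip(p):
    tp = two_year_to_one_year(p)
    assert abs(1.0 - (1.0 - tp) ** 2 - p) < 1e-12


# ------------------------------------------------------------------ prevalence

def test_starting_prevalence_normalised(small_bundle):
    prev = small_bundle.prevalence
    sums = prev.groupby(["sex", "age"])["prevalence"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    # disease states taper to zero at age 35
    at35 = prev[(prev["age"] == 35) & (prev["state"] != 1)]
    assert np.allclose(at35["prevalence"], 0.0, atol=1e-12)


def test_prevalence_monotone_for_monotone_generator():
    rng = np.random.default_rng(9)
    n = 30000
    age = rng.uniform(50, 95, n)
    sick = rng.random(n) < expit(-12.0 + 0.15 * age)
    sp = pd.DataFrame({"person_id": range(n), "wave": 1, "year": 2006,
                       "age": age, "sex": "m", "state": np.where(sick, 6, 1),
                       "death_year": np.nan, "death_cause": np.nan,
                       "entry_year": 2006})
    sp = pd.concat([sp, sp.assign(sex="f", person_id=sp["person_id"] + n)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prev = fit_starting_prevalence(sp)
    curve = prev.query("sex=='m' and state==6").sort_values("age")
    inside = curve[(curve["age"] >= 50) & (curve["age"] <= 95)]
    assert (np.diff(inside["prevalence"]) > -1e-9).all()


# ------------------------------------------------------------- state mortality

def test_state_mortality_odds_recovery():
    rng = np.random.default_rng(13)
    n = 40000
    age = rng.uniform(60, 95, n)
    state = rng.choice([1, 6], n, p=[0.8, 0.2])
    eta = -3.5 + 0.08 * (age - 75) + np.log(2.0) * (state == 6)
    dead = rng.random(n) < expit(eta)
    pairs = pd.DataFrame({
        "person_id": range(n), "wave": 1, "year": 2006, "age_mid": age,
        "female": 0.0, "sex": "m", "from_state": state,
        "to_state": np.where(dead, DEATH_NONCVD, state),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        odds = estimate_state_mortality_odds(pairs)
    assert abs(odds.odds_ratios().loc[6, "noncvd"] - 2.0) < 0.25
    assert (odds.odds_ratios() > 0).all().all()


# -------------------------------------------------------- mortality projection

def test_project_mortality_construction():
    flat = generate_mortality_series(horizon=6)
    flat.loc[:, "value"] = flat.groupby(["sex", "age_band", "cause"])["value"].transform("first")
    proj = project_mortality(flat, 2030)
    spread = proj.groupby(["sex", "age_band", "cause"])["value"].agg(
        lambda v: v.max() / v.min())
    assert np.allclose(spread, 1.0, atol=1e-9)

    from demproj.cohort import MortalityTrend
    two = generate_mortality_series(MortalityTrend(0.02, 0.02, 0.02, 0.02), horizon=6)
    proj2 = project_mortality(two, 2030)
    wide = proj2.pivot_table(index=["sex", "age_band", "cause"], columns="year",
                             values="value")
    np.testing.assert_allclose(wide[2030] / wide[2020], 0.98**10, rtol=1e-9)
    assert (proj2["value"] > 0).all()

    with pytest.raises(ValueError, match="10 years"):
        project_mortality(two[two["year"] > 2008], 2030)


# ------------------------------------------------------------- transition sets

@pytest.fixture(scope="module")
def tsets(small_bundle):
    surf = small_bundle.mortality_surface
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in ("none", "decline-1.1pct", "decline-2pct", "estimated"):
            spec = ScenarioSpec(incidence_trend=name, horizon_year=2030)
            out[name] = build_transition_set(
                small_bundle.tp_table, small_bundle.trend, surf,
                small_bundle.state_odds, spec, small_bundle.prevalence)
    return out


def test_rows_sum_to_one(tsets):
    for tset in tsets.values():
        for y in (2006, 2018, 2030):
            assert np.allclose(tset[y].sum(axis=3), 1.0, atol=1e-10)
            assert tset[y].min() >= 0 and tset[y].max() <= 1


def test_no_decline_scenario_is_calendar_constant(tsets):
    t = tsets["none"]
    dem_entries_2006 = t[2006][:, :, 0, 5]
    dem_entries_2030 = t[2030][:, :, 0, 5]
    # death probabilities still trend, but dementia-incidence entries do not
    np.testing.assert_allclose(dem_entries_2006, dem_entries_2030, atol=1e-12)


def test_incidence_odds_scaled_by_or_power(tsets):
    t = tsets["estimated"]
    p0 = t[2006][:, :, 0, 5]
    p10 = t[2016][:, :, 0, 5]
    mask = p0 > 1e-8
    odds0 = p0[mask] / (1 - p0[mask])
    odds10 = p10[mask] / (1 - p10[mask])
    np.testing.assert_allclose(odds10 / odds0, 0.973**10, rtol=1e-9)
    assert np.isclose(0.973**10, 0.761, atol=5e-4)


def test_scenario_monotonicity(tsets):
    """Dementia-incidence TPs: none >= 1.1%/yr >= 2%/yr >= estimated 2.7%."""
    order = ["none", "decline-1.1pct", "decline-2pct", "estimated"]
    for y in range(2007, 2031):
        prev = None
        for name in order:
            cur = tsets[name][y][:, :, :, 5].sum() + tsets[name][y][:, :, :, 6].sum()
            if prev is not None:
                assert cur <= prev + 1e-12
            prev = cur


def test_cvd_freeze_scenario(small_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = build_transition_set(
            small_bundle.tp_table, small_bundle.trend,
            small_bundle.mortality_surface, small_bundle.state_odds,
            ScenarioSpec(incidence_trend="estimated", horizon_year=2020),
            small_bundle.prevalence)
        frozen = build_transition_set(
            small_bundle.tp_table, small_bundle.trend,
            small_bundle.mortality_surface, small_bundle.state_odds,
            ScenarioSpec(incidence_trend="estimated", cvd_freeze_year=2014,
                         horizon_year=2020, name="cvd-freeze"),
            small_bundle.prevalence)
    cvd_entry = (slice(None), slice(None), 0, 1)  # healthy -> CVD-only
    for y in (2006, 2010, 2014):
        np.testing.assert_allclose(base[y][cvd_entry], frozen[y][cvd_entry], atol=1e-14)
    assert not np.allclose(base[2020][cvd_entry], frozen[2020][cvd_entry])


def test_odds_scaling_commutes_with_conversion_for_small_p():
    """Scaling two-year odds by the annual trend then converting to one year
    agrees with converting then scaling, to 1e-3 for P < 0.3 (the bound
    loosens to ~2.5e-3 when a decade of trend is applied at once; see the
    methods note)."""
    P = np.linspace(0.001, 0.299, 100)

    def commute_gap(f):
        a = two_year_to_one_year(P * f / (1 - P + P * f))
        p1 = two_year_to_one_year(P)
        b = p1 * f / (1 - p1 + p1 * f)
        return np.max(np.abs(a - b))

    assert commute_gap(0.973) < 1e-3
    assert commute_gap(0.973**10) < 2.5e-3


def test_scenario_spec_validation():
    with pytest.raises(ValueError, match="valid"):
        ScenarioSpec(incidence_trend="bogus")
    with pytest.raises(ValueError, match="horizon"):
        ScenarioSpec(horizon_year=1999)
    assert ScenarioSpec(incidence_trend=0.98).trend_or() == 0.98
    est = trend_from_coef(np.log(0.973), 0.001)
    assert np.isclose(ScenarioSpec().trend_or(est), 0.973)
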