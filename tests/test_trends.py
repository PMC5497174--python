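"""Calendar-trend estimators: scale conventions, degenerate cases, the
joint model's building blocks, and trend extraction from predictions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from demproj.ascertain import ascertain
from demproj.cohort import generate_cohort
from demproj.jointmodel import JointCognitionEventModel, fit_linear_mixed
from demproj.trends import (CompetingRisksTrendModel, NaiveTrendModel,
                            TrendEstimate, adjust_trend_for_risk_factors,
                            build_person_epochs, extract_calendar_trend,
                            trend_from_coef)
from conftest import small_config


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds, res = small_dataset
    naive = NaiveTrendModel().fit(ds.panel, res.statuses)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        competing = CompetingRisksTrendModel().fit(ds.panel, res.statuses)
    return ds, res, naive, competing


def test_trend_estimate_contract():
    t = trend_from_coef(np.log(0.973), 0.001)
    assert np.isclose(t.odds_ratio_per_year, 0.973)
    assert np.isclose(t.relative_annual_decline_pct, 2.7)
    assert t.ci95[0] < 0.973 < t.ci95[1]
    with pytest.raises(ValueError):
        TrendEstimate(odds_ratio_per_year=1.0, ci95=(1.1, 1.2), se_log=0.1)


def test_epoch_and_year_scales_agree(fitted):
    """A per-epoch (two-year) parameterisation reports the same per-year OR:
    the squared per-year OR equals the fitted two-year OR."""
    ds, res, naive, _ = fitted
    epoch = NaiveTrendModel(time_unit="epoch").fit(ds.panel, res.statuses)
    assert np.isclose(epoch.trend_.odds_ratio_per_year,
                      naive.trend_.odds_ratio_per_year, atol=1e-10)
    two_year_or = np.exp(epoch.coef_["year_c"])
    assert np.isclose(epoch.trend_.odds_ratio_per_year**2, two_year_or, atol=1e-10)


def test_no_incident_cases_is_an_error(fitted):
    ds, res, *_ = fitted
    st = res.statuses.copy()
    st["is_case"] = False
    st["onset_year"] = np.nan
    with pytest.raises(ValueError, match="incident"):
        NaiveTrendModel().fit(ds.panel, st)


def test_competing_risks_equals_naive_without_deaths(fitted):
    """With death information removed the multinomial collapses onto the
    binary model."""
    ds, res, *_ = fitted
    deathless = ds.panel.copy()
    deathless["death_year"] = np.nan
    deathless["death_cause"] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nv = NaiveTrendModel().fit(deathless, res.statuses)
        cr = CompetingRisksTrendModel().fit(deathless, res.statuses)
    assert np.isclose(cr.trend_.odds_ratio_per_year,
                      nv.trend_.odds_ratio_per_year, atol=2e-4)


def test_epoch_probabilities_normalised(fitted):
    *_, competing = fitted
    p = competing.epoch_probabilities(80.0, "f", 2007.0)
    assert np.isclose(p.sum(), 1.0, atol=1e-12)
    assert (p >= 0).all()
    cif = competing.cumulative_incidence(75.0, "m", 2006.0, n_epochs=5)
    assert 0 <= cif <= 1


def test_naive_trend_covers_null_when_truth_is_flat():
    """Generator with per-year OR 1.0 and non-informative dropout: the CI
    covers 1.0 in most replicates."""
    hits = 0
    for seed in (101, 102, 103, 104):
        cfg = small_config(seed=seed, true_incidence_trend_or=1.0)
        cfg.dropout_params = (0.11, 0.0)
        cfg.rf_trends = {"smoking_quit_per_epoch": 0.0,
                         "inactivity_logit_per_year": 0.0,
                         "hypertension_logit_per_year": 0.0}
        ds = generate_cohort(cfg)
        res = ascertain(ds.panel)
        t = NaiveTrendModel().fit(ds.panel, res.statuses).trend_
        hits += t.ci95[0] <= 1.0 <= t.ci95[1]
    assert hits >= 3


def _synthetic_predictions(n=4000, beta_year=np.log(0.973), rf_effect=0.0,
                           rf_trend=0.0, seed=0):
    rng = np.random.default_rng(seed)
    year = rng.integers(2003, 2012, n).astype(float)
    age = rng.uniform(52, 95, n)
    female = rng.integers(0, 2, n).astype(float)
    smoking = (rng.random(n) < expit(-1.2 + rf_trend * (year - 2006))).astype(float)
    eta = -4 + 0.08 * (age - 75) + 0.2 * female + beta_year * (year - 2006) \
        + rf_effect * smoking
    return pd.DataFrame({
        "person_id": np.arange(n), "year_mid": year, "age_mid": age,
        "female": female, "smoking": smoking, "p_dementia": expit(eta)})


def test_extraction_recovers_generating_coefficient():
    pred = _synthetic_predictions()
    est = extract_calendar_trend(pred)
    assert abs(est.odds_ratio_per_year - 0.973) < 1e-3
    assert abs(est.relative_annual_decline_pct - 2.7) < 0.2


def test_extraction_null_covers_one():
    pred = _synthetic_predictions(beta_year=0.0, seed=3)
    # predictions are noiseless logits: the coefficient is numerically zero
    est = extract_calendar_trend(pred)
    assert est.ci95[0] <= 1.0 <= est.ci95[1] or abs(est.odds_ratio_per_year - 1) < 1e-6


def test_extraction_invariant_to_calendar_recentring():
    pred = _synthetic_predictions(seed=5)
    shifted = pred.copy()
    shifted["year_mid"] += 7.0
    a = extract_calendar_trend(pred).odds_ratio_per_year
    b = extract_calendar_trend(shifted).odds_ratio_per_year
    assert np.isclose(a, b, atol=1e-10)


def test_extraction_clips_degenerate_probabilities():
    pred = _synthetic_predictions(seed=6)
    pred.loc[:3, "p_dementia"] = 0.0
    with pytest.warns(UserWarning, match="clipped"):
        extract_calendar_trend(pred)


def test_attenuation_definition_and_signs():
    """Risk-factor adjustment: attenuation is 100 x (1 - b_adj/b_unadj) on
    the log-odds scale; mediated trends attenuate, flat risk factors do not."""
    mediated = _synthetic_predictions(rf_effect=0.8, rf_trend=-0.25, seed=8)
    res = adjust_trend_for_risk_factors(mediated, rf_columns=["smoking"])
    b0 = np.log(res.unadjusted.odds_ratio_per_year)
    b1 = np.log(res.adjusted.odds_ratio_per_year)
    assert np.isclose(res.attenuation_pct, 100 * (1 - b1 / b0), atol=1e-9)
    assert 0 < res.attenuation_pct < 100

    flat = _synthetic_predictions(rf_effect=0.8, rf_trend=0.0, seed=9)
    res2 = adjust_trend_for_risk_factors(flat, rf_columns=["smoking"])
    assert abs(res2.attenuation_pct) < 8.0


def test_linear_mixed_model_against_statsmodels():
    """The EM mixed-model fit agrees with statsmodels MixedLM (independent
    oracle) on simulated random-intercept/random-slope data."""
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    n, per = 300, 5
    pidx = np.repeat(np.arange(n), per)
    t = np.tile(np.arange(per, dtype=float) * 2, n)
    x1 = rng.normal(size=n)[pidx]
    b0 = rng.normal(0, 0.7, n)
    b1 = rng.normal(0, 0.08, n)
    y = 1.0 - 0.5 * x1 - 0.05 * t + b0[pidx] + b1[pidx] * t + rng.normal(0, 0.4, n * per)
    X = np.column_stack([np.ones(n * per), x1, t])

    beta, sigma2, Sigma, ll = fit_linear_mixed(X, y, pidx, t, n_iter=500)

    df = pd.DataFrame({"y": y, "x1": x1, "t": t, "g": pidx})
    m = sm.MixedLM.from_formula("y ~ x1 + t", groups="g", re_formula="~t", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = m.fit(reml=False)
    np.testing.assert_allclose(beta, fit.fe_params.to_numpy(), atol=2e-3)
    np.testing.assert_allclose(np.sqrt(sigma2), np.sqrt(fit.scale), atol=2e-3)
    np.testing.assert_allclose(Sigma, fit.cov_re.to_numpy() * 1.0, atol=5e-3)


@pytest.fixture(scope="module")
def joint_fit(small_dataset):
    ds, res = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        jm = JointCognitionEventModel(n_quad=5, max_iter=30, tol=0.05).fit(
            ds.panel, res.statuses, res.zscores)
        pred = jm.predict_dementia_probability(ds.panel, res.statuses)
    return ds, res, jm, pred


def test_joint_loglik_ascends(joint_fit):
    *_, jm, _ = joint_fit
    path = np.array(jm.loglik_path_)
    assert path[-1] >= path[0]
    assert (np.diff(path) > -1e-4 * np.abs(path[:-1])).all()


def test_joint_predictions_are_probabilities(joint_fit):
    *_, pred = joint_fit
    assert pred["p_dementia"].between(0, 1).all()
    # dropped-out epochs are present: the correction the model exists for
    assert (~pred["under_observation"]).sum() > 0


def test_joint_predictions_track_observed_decline(joint_fit):
    """People whose observed scores decline steeply get higher predicted
    onset probabilities than flat-trajectory people (negative association)."""
    ds, res, jm, pred = joint_fit
    z = res.zscores.dropna(subset=["mean_z"])
    slopes = z.groupby("person_id").apply(
        lambda g: np.polyfit(g["year"], g["mean_z"], 1)[0] if len(g) >= 3 else np.nan,
        include_groups=False).dropna()
    p = pred.groupby("person_id")["p_dementia"].mean()
    joined = pd.concat([slopes.rename("slope"), p], axis=1).dropna()
    r = np.corrcoef(joined["slope"], np.log(joined["p_dementia"]))[0, 1]
    assert r < -0.1


def test_joint_prediction_calibration(joint_fit):
    """Mean predicted incidence among observed risk epochs is close to the
    observed incidence in those epochs."""
    ds, res, jm, pred = joint_fit
    ep = build_person_epochs(ds.panel, res.statuses)
    obs_rate = (ep["outcome"] == "dementia").mean()
    stay = pred[pred["under_observation"]]
    assert 0.5 * obs_rate < stay["p_dementia"].mean() < 2.0 * obs_rate


def truth_statuses(truth_persons):
    """Oracle statuses straight from the generator's ground truth."""
    tp = truth_persons
    prevalent = (tp["true_onset_year"] <= tp["entry_year"]).fillna(False)
    return pd.DataFrame({
        "person_id": tp["person_id"],
        "is_case": tp["true_dementia_ever"] == 1,
        "onset_year": tp["true_onset_year"],
        "prevalent_at_entry": prevalent,
        "ascertainment_year": np.where((tp["true_dementia_ever"] == 1) & ~prevalent,
                                       tp["true_onset_year"] + 1.0, np.nan),
        "ascertainment_wave": np.nan, "route": "", "numeracy_dependent": False,
    })


def test_joint_null_association_recovery():
    """Events generated with zero latent coupling and non-informative
    dropout: the fitted latent-value association is compatible with zero
    (fitted against the ground-truth event record, isolating the estimator
    from the operational detection gradient)."""
    cfg = small_config(seed=31)
    cfg.event_params.alpha_value = 0.0
    cfg.event_params.alpha_slope = 0.0
    cfg.event_params.threshold = 1e9
    cfg.dropout_params = (0.11, 0.0)
    ds = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ascertain(ds.panel)
        jm = JointCognitionEventModel(n_quad=5, max_iter=30, tol=0.05,
                                      model_death=False, model_dropout=False
                                      ).fit(ds.panel, truth_statuses(ds.truth_persons),
                                            res.zscores)
    se = np.sqrt(np.diag(jm.dem_cov_.to_numpy()))
    names = list(jm.dem_cov_.index)
    i = names.index("alpha_value")
    est = jm.coefs_["dementia"]["alpha_value"]
    assert abs(est) < 4 * se[i] + 0.3
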