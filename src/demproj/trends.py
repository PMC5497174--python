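"""Calendar-trend estimators for dementia incidence.

Events in a biennial panel are interval-censored at two-year waves, so all
models here are discrete-time per-epoch analogues of their continuous-time
counterparts:

* ``NaiveTrendModel`` — per-epoch logistic regression of incident dementia
  (deaths contribute their final epoch as non-events, mirroring the
  uninformative censoring of a proportional-hazards analysis; dropouts are
  censored at the last interview).
* ``CompetingRisksTrendModel`` — per-epoch multinomial regression with
  outcomes {none, dementia, death}, so death is a modelled outcome rather
  than a censored non-event.
* the joint longitudinal/time-to-event model lives in ``jointmodel``; its
  individual predictions feed :func:`extract_calendar_trend` and
  :func:`adjust_trend_for_risk_factors`.

All estimators report a per-year incidence odds ratio (``TrendEstimate``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import logit
from .cohort import BASE_YEAR

ANALYSIS_WAVES = (1, 2, 3, 4, 5, 6)

RF_COLUMNS = ["smoking", "inactivity", "current_hypertension",
              "midlife_obesity", "midlife_hypertension", "midlife_diabetes"]


@dataclass
class TrendEstimate:
    """Per-year incidence odds ratio with a 95% confidence interval."""

    odds_ratio_per_year: float
    ci95: tuple[float, float]
    se_log: float
    model_kind: str = ""
    sex_specific: dict | None = None

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0 < lo <= self.odds_ratio_per_year <= hi):
            raise ValueError("trend CI must bracket the odds ratio and be positive")

    @property
    def relative_annual_decline_pct(self) -> float:
        return 100.0 * (1.0 - self.odds_ratio_per_year)

    def to_dict(self) -> dict:
        return {
            "odds_ratio_per_year": self.odds_ratio_per_year,
            "ci95": list(self.ci95),
            "se_log": self.se_log,
            "relative_annual_decline_pct": self.relative_annual_decline_pct,
            "model_kind": self.model_kind,
        }


def trend_from_coef(coef: float, se: float, model_kind: str = "") -> TrendEstimate:
    return TrendEstimate(
        odds_ratio_per_year=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.959964 * se)), float(np.exp(coef + 1.959964 * se))),
        se_log=float(se),
        model_kind=model_kind,
    )


# ---------------------------------------------------------------------------
# person-epoch risk sets
# ---------------------------------------------------------------------------

def build_person_epochs(
    panel: pd.DataFrame,
    statuses: pd.DataFrame,
    analysis_waves: tuple = ANALYSIS_WAVES,
) -> pd.DataFrame:
    """Pooled two-year risk epochs (wave e -> wave e+1).

    One row per person per epoch in which the person was interviewed at the
    epoch's first wave, was free of ascertained dementia at its start, and
    either reached the next wave, had dementia onset (mid-point dated) inside
    the epoch, or died inside the epoch.  Prevalent cases are excluded.
    Dropout censors at the last interview.
    """
    waves = sorted(analysis_waves)
    obs = panel[panel["wave"].isin(waves)].copy()
    st = statuses.set_index("person_id")
    obs["onset_year"] = obs["person_id"].map(st["onset_year"])
    obs["prevalent"] = obs["person_id"].map(st["prevalent_at_entry"]).fillna(False).astype(bool)

    e = obs[obs["wave"] < waves[-1]].copy()
    e = e[~e["prevalent"]]
    e["year0"] = e["year"]
    e["year_mid"] = e["year0"] + 1.0
    e["age_mid"] = e["age"] + 1.0
    key_next = set(zip(obs["person_id"], obs["wave"]))
    e["has_next"] = [(p, w + 1) in key_next for p, w in zip(e["person_id"], e["wave"])]

    # at risk at epoch start: no ascertained onset on or before year0
    e = e[e["onset_year"].isna() | (e["onset_year"] > e["year0"])]

    dem = e["onset_year"].notna() & (e["onset_year"] > e["year0"]) & (e["onset_year"] <= e["year0"] + 2)
    dy = e["death_year"]
    death = ~dem & dy.notna() & (dy > e["year0"]) & (dy <= e["year0"] + 2)
    none = ~dem & ~death & e["has_next"]
    e["outcome"] = np.select([dem, death], ["dementia", "death"], default="none")
    e = e[dem | death | none].copy()

    e["female"] = (e["sex"] == "f").astype(float)
    e["year_c"] = e["year_mid"] - BASE_YEAR
    e["age_c"] = (e["age_mid"] - 75.0) / 10.0
    e["time_mid"] = e["year_mid"] - e["entry_year"]
    keep = [
        "person_id", "wave", "year0", "year_mid", "year_c", "age_mid", "age_c",
        "time_mid", "female", "sex", "education", "outcome", "has_next",
    ] + [c for c in RF_COLUMNS if c in e.columns]
    return e[keep].reset_index(drop=True)


def _design(e: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "age_c": e["age_c"],
            "age_c2": e["age_c"] ** 2,
            "female": e["female"],
            "age_c:female": e["age_c"] * e["female"],
            "age_c2:female": e["age_c"] ** 2 * e["female"],
            "year_c": e["year_c"],
        },
        index=e.index,
    )
    return X


class _ParamsMixin:
    """Minimal get_params/set_params so estimators compose with sklearn tooling."""

    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self


class NaiveTrendModel(_ParamsMixin):
    """Discrete-time per-epoch logistic model of incident dementia.

    Covariates: age, age squared, sex, their interactions, and calendar time.
    ``time_unit='year'`` puts calendar time in years (the coefficient is the
    per-year log odds ratio); ``'epoch'`` uses two-year epochs, in which case
    the reported per-year OR is the square root of the fitted epoch OR.
    """

    _param_names = ("time_unit", "analysis_waves")

    def __init__(self, time_unit: str = "year", analysis_waves: tuple = ANALYSIS_WAVES):
        if time_unit not in ("year", "epoch"):
            raise ValueError("time_unit must be 'year' or 'epoch'")
        self.time_unit = time_unit
        self.analysis_waves = analysis_waves

    def fit(self, panel: pd.DataFrame, statuses: pd.DataFrame):
        e = build_person_epochs(panel, statuses, self.analysis_waves)
        y = (e["outcome"] == "dementia").astype(float)
        if y.sum() == 0:
            raise ValueError("no incident dementia cases in the risk set")
        X = _design(e)
        if self.time_unit == "epoch":
            X["year_c"] = X["year_c"] / 2.0
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception as err:  # pragma: no cover - statsmodels raises various
            raise RuntimeError(f"trend model failed to converge ({err}); "
                               "consider a larger sample") from err
        if not np.all(np.isfinite(res.bse)):
            raise RuntimeError("separation in trend model; consider a larger sample")
        self.coef_ = res.params
        self.cov_ = res.cov_params()
        self.n_epochs_ = len(e)
        self.n_events_ = int(y.sum())
        scale = 0.5 if self.time_unit == "epoch" else 1.0
        self.trend_ = trend_from_coef(res.params["year_c"] * scale,
                                      res.bse["year_c"] * scale, "naive")
        self.result_ = res
        return self

    @property
    def model_kind(self) -> str:
        return "naive"


class CompetingRisksTrendModel(_ParamsMixin):
    """Per-epoch multinomial model: no event / incident dementia / death.

    In the naive logistic model deaths sit in the non-event denominator, and
    their secular decline mechanically flattens the estimated incidence
    trend.  Modelling death as its own outcome conditions it out of the
    dementia denominator; the reported trend is the per-year OR on the
    dementia category (the discrete-time analogue of not censoring deaths
    uninformatively).
    """

    _param_names = ("analysis_waves",)

    OUTCOMES = ("none", "dementia", "death")

    def __init__(self, analysis_waves: tuple = ANALYSIS_WAVES):
        self.analysis_waves = analysis_waves

    def fit(self, panel: pd.DataFrame, statuses: pd.DataFrame):
        e = build_person_epochs(panel, statuses, self.analysis_waves)
        if (e["outcome"] == "dementia").sum() == 0:
            raise ValueError("no incident dementia cases in the risk set")
        codes = pd.Categorical(e["outcome"], categories=list(self.OUTCOMES)).codes
        X = _design(e)
        present = sorted(set(codes))
        remap = {c: i for i, c in enumerate(present)}
        y = np.array([remap[c] for c in codes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, X).fit(disp=0, maxiter=200, method="newton")
        names = [self.OUTCOMES[c] for c in present if c != 0]
        params = pd.DataFrame(np.asarray(res.params), index=X.columns, columns=names)
        if not np.all(np.isfinite(np.asarray(res.bse))):
            raise RuntimeError("separation in competing-risks model; consider a larger sample")
        bse = pd.DataFrame(np.asarray(res.bse), index=X.columns, columns=names)
        self.coef_ = params
        self.bse_ = bse
        self.n_epochs_ = len(e)
        self.result_ = res
        self.trend_ = trend_from_coef(params.loc["year_c", "dementia"],
                                      bse.loc["year_c", "dementia"], "competing-risks")
        return self

    def epoch_probabilities(self, age: float, sex: str, year_mid: float) -> pd.Series:
        """Model margins: per-epoch outcome probabilities for one stratum."""
        row = pd.DataFrame(
            {"age_c": [(age + 1 - 75.0) / 10.0], "female": [1.0 if sex == "f" else 0.0],
             "year_c": [year_mid - BASE_YEAR]}
        )
        X = _design(pd.DataFrame({"age_c": row["age_c"], "female": row["female"],
                                  "year_c": row["year_c"]}))
        eta = X.to_numpy() @ self.coef_.to_numpy()  # (1, k-1)
        expeta = np.exp(eta)
        denom = 1.0 + expeta.sum()
        probs = {"none": 1.0 / denom}
        for j, name in enumerate(self.coef_.columns):
            probs[name] = float(expeta[0, j] / denom)
        return pd.Series(probs)

    def cumulative_incidence(self, age: float, sex: str, start_year: float,
                             n_epochs: int = 5) -> float:
        """Model-implied probability of dementia within ``n_epochs`` two-year
        epochs, treating death as a competing exit."""
        surv, cif = 1.0, 0.0
        for k in range(n_epochs):
            p = self.epoch_probabilities(age + 2 * k, sex, start_year + 2 * k + 1)
            cif += surv * p.get("dementia", 0.0)
            surv *= p.get("none", 1.0)
        return cif

    @property
    def model_kind(self) -> str:
        return "competing-risks"


# ---------------------------------------------------------------------------
# trend extraction from individual predictions
# ---------------------------------------------------------------------------

PREDICTION_TERMS = ["const", "female", "age_c", "age_c2", "age_c:female", "age_c2:female"]


def _prediction_design(pred: pd.DataFrame, extra: list[str] | None = None) -> pd.DataFrame:
    age_c = (pred["age_mid"] - 75.0) / 10.0
    female = pred["female"].astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "female": female,
            "age_c": age_c,
            "age_c2": age_c**2,
            "age_c:female": age_c * female,
            "age_c2:female": age_c**2 * female,
            "year_c": pred["year_mid"] - BASE_YEAR,
        },
        index=pred.index,
    )
    for c in extra or []:
        X[c] = pred[c].astype(float)
    return X


def extract_calendar_trend(pred: pd.DataFrame, eps: float = 1e-6,
                           extra_terms: list[str] | None = None) -> TrendEstimate:
    """Per-year trend OR from individual per-epoch dementia probabilities.

    Linear regression of the log odds of the predicted probability on sex,
    age, age squared, their interactions with sex, and calendar year.
    Probabilities at 0 or 1 are clipped to ``eps`` with a warning.
    """
    p = pred["p_dementia"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(f"{np.sum((p <= 0) | (p >= 1))} probabilities clipped to [{eps}, 1-{eps}]")
    y = logit(p, eps=eps)
    X = _prediction_design(pred, extra_terms)
    dropped = []
    Xn = X.to_numpy()
    rank = np.linalg.matrix_rank(Xn)
    if rank < X.shape[1]:
        # drop collinear columns greedily, never the calendar term
        keep = []
        for c in X.columns:
            trial = keep + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                keep.append(c)
            else:
                dropped.append(c)
        if dropped:
            warnings.warn(f"dropping collinear terms: {dropped}")
        X = X[keep]
    res = sm.OLS(y, X).fit()
    est = trend_from_coef(res.params["year_c"], res.bse["year_c"], "prediction-regression")
    est.sex_specific = {}
    for sex, female in (("m", 0.0), ("f", 1.0)):
        sub = pred[pred["female"] == female]
        if len(sub) > 50:
            Xs = _prediction_design(sub, extra_terms).drop(
                columns=["female", "age_c:female", "age_c2:female"], errors="ignore")
            Xs = Xs[[c for c in Xs.columns if c not in dropped]]
            rs = sm.OLS(logit(sub["p_dementia"].to_numpy(), eps=eps), Xs).fit()
            est.sex_specific[sex] = trend_from_coef(rs.params["year_c"], rs.bse["year_c"],
                                                    f"prediction-regression[{sex}]")
    return est


@dataclass
class AdjustedTrend:
    unadjusted: TrendEstimate
    adjusted: TrendEstimate
    attenuation_pct: float  # 100 x (1 - beta_adj / beta_unadj), log-odds scale


def adjust_trend_for_risk_factors(pred: pd.DataFrame,
                                  rf_columns: list[str] | None = None,
                                  eps: float = 1e-6) -> AdjustedTrend:
    """Risk-factor-adjusted calendar trend and percent attenuation.

    Refits the prediction regression with time-varying risk-factor terms and
    reports how much of the calendar log-odds coefficient they absorb.
    """
    rf_columns = [c for c in (rf_columns or RF_COLUMNS) if c in pred.columns]
    base = extract_calendar_trend(pred, eps=eps)
    adj = extract_calendar_trend(pred, eps=eps, extra_terms=rf_columns)
    b0 = np.log(base.odds_ratio_per_year)
    b1 = np.log(adj.odds_ratio_per_year)
    att = 100.0 * (1.0 - b1 / b0) if b0 != 0 else np.nan
    return AdjustedTrend(unadjusted=base, adjusted=adj, attenuation_pct=float(att))


def fit_naive_trend(panel, statuses, **kw) -> NaiveTrendModel:
    return NaiveTrendModel(**kw).fit(panel, statuses)


def fit_competing_risks_trend(panel, statuses, **kw) -> CompetingRisksTrendModel:
    return CompetingRisksTrendModel(**kw).fit(panel, statuses)
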