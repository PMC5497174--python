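"""Operational dementia case ascertainment from a cognitive-ageing panel.

Caseness is defined without clinical adjudication, from three routes:

1. impairment (z <= -1.5, education-standardised against the age-50-80
   reference population) in two or more cognitive domains, together with
   impairment in one or more activities of daily living (ADL);
2. informant questionnaire (IQCODE) score >= 3.6 together with ADL
   impairment, for proxy interviews; or
3. self- or informant-reported doctor diagnosis of dementia.

Transient impairments are rescinded: a cognitive impairment followed by an
improvement of >= 1 SD in the mean standardised score at the consecutive
wave, or a single-wave ADL impairment with full recovery at all later
observed waves, does not count.  Impairments at the final analysis wave are
resolved against the auxiliary wave when it is present.

Onset is dated to the mid-point between the wave at which dementia is first
ascertained and the latest previous assessment; when caseness hinges on the
numeracy test (administered only at waves 1, 4 and 6) the mid-point is taken
between consecutive numeracy-bearing waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAIN_DEF = {
    "concentration": ("orientation",),
    "memory": ("immediate_recall", "delayed_recall"),
    "executive": ("fluency", "numeracy", "literacy"),
}


@dataclass
class AscertainmentConfig:
    z_cut: float = -1.5            # domain impairment: z <= z_cut (inclusive)
    improvement_sd: float = 1.0    # rescind if mean z improves by >= this at next wave
    iqcode_cut: float = 3.6        # IQCODE impairment: score >= cut (inclusive)
    min_tests: int = 3             # valid assessment requires >= this many tests
    reference_age_range: tuple[float, float] = (50.0, 80.0)
    analysis_waves: tuple = (1, 2, 3, 4, 5, 6)


@dataclass
class AscertainmentResult:
    zscores: pd.DataFrame
    cognitive_flags: pd.DataFrame
    functional_flags: pd.DataFrame
    statuses: pd.DataFrame
    config: AscertainmentConfig = field(default_factory=AscertainmentConfig)


def _reference_mask(panel: pd.DataFrame, cfg: AscertainmentConfig) -> pd.Series:
    lo, hi = cfg.reference_age_range
    return panel["age"].between(lo, hi) & panel["wave"].isin(cfg.analysis_waves)


def standardize_domain_scores(panel: pd.DataFrame, config: AscertainmentConfig | None = None) -> pd.DataFrame:
    """Education-stratified z-scores per cognitive domain.

    Each raw test is standardised against the ages-50-80 reference stratum of
    the same education level; domain composites (mean of available tests) are
    re-standardised within (education, availability pattern) so their scale is
    an honest reference-population SD regardless of which tests were offered
    at a wave.  Also returns the executive composite excluding numeracy
    (needed to date caseness that hinges on the numeracy test) and the mean z
    across observed domains (the longitudinal outcome of the joint model).
    """
    cfg = config or AscertainmentConfig()
    out = panel[["person_id", "wave", "year", "age", "sex", "education", "n_tests_answered"]].copy()
    ref = _reference_mask(panel, cfg)
    if not ref.any():
        raise ValueError("empty age-50-80 reference population")

    tests = [c.removeprefix("score_") for c in panel.columns if c.startswith("score_")]
    ztest = {}
    for t in tests:
        col = panel[f"score_{t}"]
        stats = col[ref].groupby(panel.loc[ref, "education"]).agg(["mean", "std", "count"])
        # a stratum is required only where the test was actually administered
        for lev in panel.loc[col.notna(), "education"].unique():
            if lev not in stats.index or stats.loc[lev, "count"] == 0 or np.isnan(stats.loc[lev, "mean"]):
                raise ValueError(f"empty reference stratum: education={lev}, test={t}")
            if not stats.loc[lev, "std"] > 0:
                raise ValueError(f"zero reference SD: education={lev}, test={t}")
        if col.notna().any():
            mu = panel["education"].map(stats["mean"])
            sd = panel["education"].map(stats["std"])
            ztest[t] = (col - mu) / sd
        else:
            ztest[t] = col

    def composite(test_list, name):
        zs = pd.concat([ztest[t] for t in test_list if t in ztest], axis=1)
        avail = (~zs.isna()).astype(int)
        pattern = avail.astype(str).agg("".join, axis=1)
        raw = zs.mean(axis=1)
        key = pd.Series(list(zip(panel["education"], pattern)), index=panel.index)
        grp = raw[ref].groupby(key[ref])
        mu = key.map(grp.mean())
        sd = key.map(grp.std())
        # patterns unseen in the reference stratum (or degenerate): leave on
        # the averaged-test scale, which is already approximately standardised
        z = np.where(sd > 0, (raw - mu) / sd, raw)
        out[name] = np.where(raw.isna(), np.nan, z)

    composite(DOMAIN_DEF["concentration"], "z_concentration")
    composite(DOMAIN_DEF["memory"], "z_memory")
    composite(DOMAIN_DEF["executive"], "z_executive")
    composite(tuple(t for t in DOMAIN_DEF["executive"] if t != "numeracy"), "z_executive_no_numeracy")

    zcols = ["z_concentration", "z_memory", "z_executive"]
    out["n_domains_observed"] = out[zcols].notna().sum(axis=1)
    out["mean_z"] = out[zcols].mean(axis=1)
    out["valid_assessment"] = out["n_tests_answered"] >= cfg.min_tests
    return out


def classify_cognitive_impairment(zscores: pd.DataFrame, config: AscertainmentConfig | None = None) -> pd.DataFrame:
    """Cognitive impairment (>= 2 impaired domains) with transience rescinded.

    A domain is impaired iff its z-score is <= the cut (boundary inclusive).
    Impairment at wave w is transient when the mean standardised score rises
    by >= 1 SD at wave w+1 (the consecutive wave; the auxiliary wave resolves
    the final analysis wave).  Only valid assessments are classified.
    """
    cfg = config or AscertainmentConfig()
    z = zscores.sort_values(["person_id", "wave"]).reset_index(drop=True)
    if (z.groupby("person_id")["wave"].diff().dropna() <= 0).any():
        raise ValueError("waves must be strictly increasing within person")
    zcols = ["z_concentration", "z_memory", "z_executive"]
    impaired = (z[zcols] <= cfg.z_cut).sum(axis=1)
    imp_no_num = (
        (z[["z_concentration", "z_memory", "z_executive_no_numeracy"]] <= cfg.z_cut).sum(axis=1)
    )
    flags = z[["person_id", "wave"]].copy()
    flags["cognitive_impairment_raw"] = (impaired >= 2) & z["valid_assessment"]
    flags["cognitive_impairment_without_numeracy"] = (imp_no_num >= 2) & z["valid_assessment"]

    nxt = z.groupby("person_id")[["wave", "mean_z"]].shift(-1)
    consecutive = nxt["wave"] == z["wave"] + 1
    improved = consecutive & ((nxt["mean_z"] - z["mean_z"]) >= cfg.improvement_sd)
    flags["transient_cognitive"] = flags["cognitive_impairment_raw"] & improved.fillna(False)
    flags["cognitive_impairment"] = flags["cognitive_impairment_raw"] & ~flags["transient_cognitive"]
    return flags


def classify_functional_impairment(panel: pd.DataFrame, config: AscertainmentConfig | None = None) -> pd.DataFrame:
    """Functional impairment (>= 1 ADL) with single-wave transience rescinded.

    The auxiliary wave beyond the analysis window contributes only recovery
    (or persistence) evidence for the final analysis wave; it never counts
    as an impairment occasion in its own right.
    """
    cfg = config or AscertainmentConfig()
    last_wave = max(cfg.analysis_waves)
    p = panel.sort_values(["person_id", "wave"]).reset_index(drop=True)
    imp_all = (p["adl_impaired_count"].fillna(0) >= 1).to_numpy()
    in_window = p["wave"].isin(cfg.analysis_waves).to_numpy()

    aux = p[~p["wave"].isin(cfg.analysis_waves) & (p["wave"] == last_wave + 1)]
    aux_imp = dict(zip(aux["person_id"], aux["adl_impaired_count"].fillna(0) >= 1))

    flags = p.loc[in_window, ["person_id", "wave"]].copy()
    imp = imp_all[in_window]
    flags["functional_impairment_raw"] = imp

    g = flags.groupby("person_id")["functional_impairment_raw"]
    n_impaired_waves = g.transform("sum")
    later_any = g.transform(lambda s: s[::-1].cumsum()[::-1].shift(-1).fillna(0)) > 0
    has_later = flags.groupby("person_id")["wave"].transform("max") > flags["wave"]
    # the final analysis wave can only be rescinded through the auxiliary wave
    aux_observed = flags["person_id"].map(lambda pid: pid in aux_imp)
    aux_recovered = flags["person_id"].map(lambda pid: not aux_imp.get(pid, True))
    is_last = flags["wave"] == flags.groupby("person_id")["wave"].transform("max")
    recovery_evidence = np.where(is_last, aux_observed & aux_recovered,
                                 has_later & ~later_any)
    flags["transient_functional"] = (
        flags["functional_impairment_raw"] & (n_impaired_waves == 1) & recovery_evidence
    )
    flags["functional_impairment"] = flags["functional_impairment_raw"] & ~flags["transient_functional"]
    return flags


_NUMERACY_WAVES = (1, 4, 6)


def ascertain_dementia(
    cognitive_flags: pd.DataFrame,
    functional_flags: pd.DataFrame,
    panel: pd.DataFrame,
    config: AscertainmentConfig | None = None,
) -> pd.DataFrame:
    """Per-person caseness, route and mid-point-dated onset year.

    Route precedence (reporting only; any route establishes caseness):
    doctor diagnosis > IQCODE + ADL > cognitive tests + ADL.
    """
    cfg = config or AscertainmentConfig()
    waves = set(cfg.analysis_waves)
    df = panel[["person_id", "wave", "year", "iqcode", "doctor_dx_dementia"]].merge(
        cognitive_flags, on=["person_id", "wave"], how="left"
    ).merge(functional_flags, on=["person_id", "wave"], how="left")
    df = df[df["wave"].isin(waves)].sort_values(["person_id", "wave"]).reset_index(drop=True)

    func = df["functional_impairment"].astype("boolean").fillna(False).astype(bool)
    route_dx = df["doctor_dx_dementia"].fillna(0).astype(bool)
    route_iq = (df["iqcode"] >= cfg.iqcode_cut) & func  # missing IQCODE -> not impaired by IQCODE
    route_tests = df["cognitive_impairment"].astype("boolean").fillna(False).astype(bool) & func
    df["any_route"] = route_dx | route_iq | route_tests
    df["route"] = np.select(
        [route_dx, route_iq, route_tests],
        ["doctor-diagnosis", "iqcode-adl", "tests-adl"],
        default="",
    )
    # caseness hinges on numeracy when the tests route fires only because the
    # executive domain includes the numeracy test
    tests_only = route_tests & ~route_dx & ~route_iq
    no_num = df["cognitive_impairment_without_numeracy"].astype("boolean").fillna(False).astype(bool)
    df["numeracy_dependent"] = tests_only & ~no_num & df["wave"].isin(_NUMERACY_WAVES)

    first_case = df[df["any_route"]].groupby("person_id").first().reset_index()
    obs = df.groupby("person_id").agg(first_wave=("wave", "min"), first_year=("year", "min"))
    prev_assess = df.merge(first_case[["person_id", "wave"]].rename(columns={"wave": "case_wave"}),
                           on="person_id")
    prev_assess = prev_assess[prev_assess["wave"] < prev_assess["case_wave"]]
    prev_year = prev_assess.groupby("person_id")["year"].max()
    prev_numeracy = prev_assess[prev_assess["wave"].isin(_NUMERACY_WAVES)].groupby("person_id")["year"].max()

    rows = []
    for rec in first_case.itertuples(index=False):
        pid_ = rec.person_id
        prevalent = rec.wave == obs.loc[pid_, "first_wave"]
        if prevalent:
            onset = float(rec.year)
        else:
            if pid_ not in prev_year.index:
                raise ValueError(f"case person {pid_} has no prior assessment and is not at entry wave")
            if rec.numeracy_dependent and pid_ in prev_numeracy.index:
                onset = 0.5 * (rec.year + prev_numeracy.loc[pid_])
            else:
                onset = 0.5 * (rec.year + prev_year.loc[pid_])
        rows.append(
            dict(person_id=pid_, is_case=True, prevalent_at_entry=bool(prevalent),
                 onset_year=onset, route=rec.route, ascertainment_wave=int(rec.wave),
                 ascertainment_year=int(rec.year),
                 numeracy_dependent=bool(rec.numeracy_dependent))
        )
    cases = pd.DataFrame(rows)
    non = obs.index.difference(cases["person_id"] if len(cases) else [])
    noncases = pd.DataFrame(
        dict(person_id=non, is_case=False, prevalent_at_entry=False, onset_year=np.nan,
             route="", ascertainment_wave=pd.NA, ascertainment_year=pd.NA,
             numeracy_dependent=False)
    )
    statuses = pd.concat([cases, noncases], ignore_index=True).sort_values("person_id").reset_index(drop=True)
    return statuses


def ascertain(panel: pd.DataFrame, config: AscertainmentConfig | None = None) -> AscertainmentResult:
    """Run the full ascertainment pipeline on a panel."""
    cfg = config or AscertainmentConfig()
    z = standardize_domain_scores(panel, cfg)
    cog = classify_cognitive_impairment(z, cfg)
    fun = classify_functional_impairment(panel, cfg)
    statuses = ascertain_dementia(cog, fun, panel, cfg)
    return AscertainmentResult(zscores=z, cognitive_flags=cog, functional_flags=fun,
                               statuses=statuses, config=cfg)


def observed_incidence(
    panel: pd.DataFrame,
    statuses: pd.DataFrame,
    epoch_start_years: tuple = (2008, 2010),
    min_age: float = 50.0,
) -> pd.Series:
    """Crude ascertained dementia incidence per 1000 person-years by sex.

    Counts incident (non-prevalent) cases with onset inside the two-year
    epochs starting at ``epoch_start_years`` over the person-years of
    participants under observation, dementia-free and aged >= ``min_age`` at
    the epoch start.
    """
    st = statuses.set_index("person_id")
    events = pd.Series(0.0, index=["m", "f"])
    pyears = pd.Series(0.0, index=["m", "f"])
    for y0 in epoch_start_years:
        at_wave = panel[(panel["year"] == y0) & (panel["age"] >= min_age)]
        onset = at_wave["person_id"].map(st["onset_year"])
        prevalent = at_wave["person_id"].map(st["prevalent_at_entry"]).fillna(False).astype(bool)
        at_risk = at_wave[(onset.isna() | (onset > y0)) & ~prevalent]
        onset_r = at_risk["person_id"].map(st["onset_year"])
        ev = (onset_r > y0) & (onset_r <= y0 + 2)
        for sex in ("m", "f"):
            m = at_risk["sex"] == sex
            pyears[sex] += 2.0 * m.sum()
            events[sex] += (ev & m).sum()
    return 1000.0 * events / pyears
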