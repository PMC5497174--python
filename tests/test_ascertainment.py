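"""Operational case definition: standardisation, impairment rules,
transience, routes, and onset dating."""

import numpy as np
import pandas as pd
import pytest

from demproj.ascertain import (AscertainmentConfig, ascertain,
                               ascertain_dementia,
                               classify_cognitive_impairment,
                               classify_functional_impairment,
                               standardize_domain_scores)
from demproj.cohort import generate_cohort
from conftest import make_panel, reference_block, small_config


def build(records):
    return make_panel(records + reference_block())


def flags_for(panel, cfg=None):
    cfg = cfg or AscertainmentConfig()
    z = standardize_domain_scores(panel, cfg)
    cog = classify_cognitive_impairment(z, cfg)
    fun = classify_functional_impairment(panel, cfg)
    return z, cog, fun


def test_zscores_match_hand_computation():
    """Single-test concentration domain: z equals (x - mu)/sd of the
    education-matched 50-80 reference stratum."""
    recs = [dict(person_id=i, wave=1, age=60.0, education="none",
                 score_orientation=v, n_tests_answered=5)
            for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])]
    panel = build(recs)
    z = standardize_domain_scores(panel)
    in_ref = panel["age"].between(50, 80) & (panel["education"] == "none")
    ref = panel.loc[in_ref, "score_orientation"].dropna()
    mu, sd = ref.mean(), ref.std()
    got = z.set_index("person_id").loc[range(5), "z_concentration"]
    np.testing.assert_allclose(got, (np.array([1, 2, 3, 4, 5.0]) - mu) / sd,
                               atol=1e-10)


def test_reference_errors():
    recs = [dict(person_id=1, wave=1, age=60.0)]
    panel = make_panel(recs)
    panel["age"] = 95.0  # nobody in the 50-80 reference range
    with pytest.raises(ValueError, match="reference"):
        standardize_domain_scores(panel)


def test_fewer_than_three_tests_is_invalid():
    recs = [dict(person_id=1, wave=2, n_tests_answered=2)]
    z = standardize_domain_scores(build(recs))
    assert not z.set_index("person_id").loc[1, "valid_assessment"]


def test_two_domain_rule_boundary_inclusive():
    """z of exactly -1.5 in two domains is impairment; one domain is not."""
    z = pd.DataFrame({
        "person_id": [1, 2], "wave": [1, 1],
        "z_concentration": [-1.5, -1.6], "z_memory": [-1.5, 0.0],
        "z_executive": [0.0, 0.0], "z_executive_no_numeracy": [0.0, 0.0],
        "mean_z": [-1.0, -0.5], "valid_assessment": [True, True],
    })
    cog = classify_cognitive_impairment(z).set_index("person_id")
    assert cog.loc[1, "cognitive_impairment"]
    assert not cog.loc[2, "cognitive_impairment"]


def test_transient_cognitive_rescinded_on_one_sd_improvement():
    z = pd.DataFrame({
        "person_id": [1, 1, 2, 2], "wave": [1, 2, 1, 2],
        "z_concentration": [-2.0, 0.0, -2.0, -2.0],
        "z_memory": [-2.0, 0.0, -2.0, -2.0],
        "z_executive": [0.0, 0.0, 0.0, 0.0],
        "z_executive_no_numeracy": [0.0, 0.0, 0.0, 0.0],
        "mean_z": [-1.4, -0.1, -1.4, -1.4],  # person 1 improves by 1.3 SD
        "valid_assessment": True,
    })
    cog = classify_cognitive_impairment(z)
    p1 = cog[cog["person_id"] == 1].set_index("wave")
    p2 = cog[cog["person_id"] == 2].set_index("wave")
    assert p1.loc[1, "transient_cognitive"] and not p1.loc[1, "cognitive_impairment"]
    assert not p2.loc[1, "transient_cognitive"] and p2.loc[1, "cognitive_impairment"]


def test_unordered_waves_rejected():
    z = pd.DataFrame({
        "person_id": [1, 1], "wave": [2, 2], "z_concentration": [0.0, 0.0],
        "z_memory": [0.0, 0.0], "z_executive": [0.0, 0.0],
        "z_executive_no_numeracy": [0.0, 0.0], "mean_z": [0.0, 0.0],
        "valid_assessment": True,
    })
    with pytest.raises(ValueError, match="increasing"):
        classify_cognitive_impairment(z)


@pytest.mark.parametrize("counts,expect_transient,expect_any", [
    ((0, 1, 0, 0, 0, 0), True, False),   # single wave, full later recovery
    ((0, 1, 1, 0, 0, 0), False, True),   # repeated impairment stands
    ((0, 0, 0, 0, 0, 0), False, False),  # never impaired
    ((0, 0, 0, 0, 0, 1), False, True),   # final wave, no later data
])
def test_functional_transience(counts, expect_transient, expect_any):
    recs = [dict(person_id=1, wave=w + 1, adl_impaired_count=c)
            for w, c in enumerate(counts)]
    fun = classify_functional_impairment(make_panel(recs))
    assert fun["transient_functional"].any() == expect_transient
    assert fun["functional_impairment"].any() == expect_any


def test_routes_and_midpoint_dating():
    recs = []
    # person 1: doctor diagnosis at wave 4 (2008), previous assessment 2006
    for w in (1, 2, 3, 4):
        recs.append(dict(person_id=1, wave=w, doctor_dx_dementia=int(w == 4)))
    # person 2: IQCODE 3.6 + one ADL at wave 3 -> case via the IQCODE route
    for w in (1, 2, 3):
        recs.append(dict(person_id=2, wave=w, iqcode=3.6 if w == 3 else np.nan,
                         adl_impaired_count=int(w == 3), n_tests_answered=0))
    # person 3: never a case
    recs.append(dict(person_id=3, wave=1))
    st = ascertain(build(recs)).statuses.set_index("person_id")
    assert st.loc[1, "is_case"] and st.loc[1, "route"] == "doctor-diagnosis"
    assert st.loc[1, "onset_year"] == 2007.0  # midpoint of 2006 and 2008
    assert st.loc[2, "is_case"] and st.loc[2, "route"] == "iqcode-adl"
    assert not st.loc[3, "is_case"]
    assert st.loc[3, "onset_year"] is np.nan or np.isnan(st.loc[3, "onset_year"])


def test_prevalent_at_entry_flag():
    recs = [dict(person_id=1, wave=1, doctor_dx_dementia=1)]
    st = ascertain(build(recs)).statuses.set_index("person_id")
    assert bool(st.loc[1, "prevalent_at_entry"])
    assert st.loc[1, "onset_year"] == 2002.0


def test_numeracy_hinged_case_dated_between_numeracy_waves():
    """Caseness that requires the numeracy test is dated to the midpoint of
    the consecutive numeracy-bearing waves (1 -> 4: 2005)."""
    recs = []
    for w in (1, 2, 3, 4):
        recs.append(dict(
            person_id=1, wave=w,
            # memory impaired throughout; executive impaired only through
            # numeracy at wave 4
            score_immediate_recall=-9.0, score_delayed_recall=-9.0,
            score_numeracy=-9.0 if w == 4 else np.nan,
            score_fluency=0.0, score_orientation=0.0,
            adl_impaired_count=1,
        ))
    st = ascertain(build(recs)).statuses.set_index("person_id")
    row = st.loc[1]
    assert row["is_case"] and row["numeracy_dependent"]
    assert row["onset_year"] == 2005.0  # midpoint of 2002 and 2008


def test_monotonicity_more_impairment_never_removes_caseness(small_dataset):
    """Raising an ADL count never converts a case into a non-case."""
    ds, res = small_dataset
    base_cases = set(res.statuses.loc[res.statuses["is_case"], "person_id"])
    worse = ds.panel.copy()
    worse["adl_impaired_count"] = np.minimum(worse["adl_impaired_count"] + 1, 7)
    st2 = ascertain(worse).statuses
    new_cases = set(st2.loc[st2["is_case"], "person_id"])
    assert base_cases <= new_cases


def test_auxiliary_wave_only_affects_final_wave_transience(small_dataset):
    """Ascertainment with wave-7 rows appended never changes cases that were
    established by wave 5 on the same panel."""
    ds, res = small_dataset
    with_aux = res.statuses
    without = ascertain(ds.panel[ds.panel["wave"] <= 6]).statuses.set_index("person_id")
    a = with_aux[pd.to_numeric(with_aux["ascertainment_wave"],
                               errors="coerce") <= 5]
    for row in a.itertuples(index=False):
        assert without.loc[row.person_id, "is_case"]
        assert without.loc[row.person_id, "ascertainment_wave"] == row.ascertainment_wave


def test_ascertained_counts_approach_truth_as_noise_vanishes():
    cfg_noisy = small_config(seed=21)
    cfg_clean = small_config(seed=21)
    cfg_clean.measurement_sd = {k: 1e-3 for k in cfg_clean.measurement_sd}
    gaps = {}
    for name, cfg in (("noisy", cfg_noisy), ("clean", cfg_clean)):
        ds = generate_cohort(cfg)
        st = ascertain(ds.panel).statuses
        true_n = int(ds.truth_persons["true_dementia_ever"].sum())
        asc_true = st.merge(ds.truth_persons[["person_id", "true_dementia_ever"]],
                            on="person_id")
        hits = int((asc_true["is_case"] & (asc_true["true_dementia_ever"] == 1)).sum())
        gaps[name] = hits / true_n
    assert gaps["clean"] >= gaps["noisy"]
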