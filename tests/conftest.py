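import math

import numpy as np
import pandas as pd
import pytest

from demproj.ascertain import ascertain
from demproj.cohort import CohortConfig, generate_cohort
from demproj.pipeline import calibrate
from demproj.trends import trend_from_coef

SMALL_RECRUITMENT = ((3, 2006, (50, 55), 250), (4, 2008, (50, 74), 500),
                     (6, 2012, (50, 55), 250))


def small_config(seed=42, **overrides):
    return CohortConfig(n_core=2000, recruitment_waves=SMALL_RECRUITMENT,
                        seed=seed, **overrides)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced panel plus its ascertainment, shared across tests."""
    ds = generate_cohort(small_config())
    res = ascertain(ds.panel)
    return ds, res


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    """Calibration bundle on the reduced panel with a fixed trend input."""
    import warnings

    ds, res = small_dataset
    trend = trend_from_coef(math.log(0.973), 0.0013, "fixed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = calibrate(ds.panel, res, trend)
    return bundle


def make_panel(records, extra_columns=None):
    """Construct a minimal schema-conformant panel from compact records.

    Each record: dict with person_id, wave and optional overrides; sensible
    defaults fill the remaining columns.
    """
    rows = []
    for rec in records:
        wave = rec["wave"]
        row = dict(
            person_id=rec["person_id"], wave=wave, year=2000 + 2 * wave,
            age=70.0 + 2 * (wave - 1), sex="m", education="intermediate",
            score_orientation=0.0, score_immediate_recall=0.0,
            score_delayed_recall=0.0, score_fluency=0.0,
            score_numeracy=0.0 if wave in (1, 4, 6) else np.nan,
            score_literacy=0.0 if wave == 6 else np.nan,
            n_tests_answered=5 if wave in (1, 4) else (6 if wave == 6 else 4),
            adl_impaired_count=0, iqcode=np.nan, doctor_dx_dementia=0,
            cvd_status=0, smoking=0, inactivity=0, current_hypertension=0,
            midlife_obesity=0, midlife_hypertension=0, midlife_diabetes=0,
            weight=1.0, entry_wave=1, entry_year=2002, death_year=np.nan,
            death_cause=np.nan, dropout_after_wave=np.nan,
            vital_status="alive", dropped_out=0,
        )
        row.update({k: v for k, v in rec.items()})
        if extra_columns:
            row.update(extra_columns)
        rows.append(row)
    return pd.DataFrame(rows)


def reference_block(n=40, start_id=1000):
    """Unimpaired reference person-waves (ages 50-80) so education strata are
    populated; scores spread so reference SDs are positive."""
    rng = np.random.default_rng(7)
    recs = []
    for i in range(n):
        for educ in ("none", "intermediate", "higher"):
            recs.append(dict(
                person_id=start_id + i * 3 + {"none": 0, "intermediate": 1,
                                              "higher": 2}[educ],
                wave=1, age=50.0 + (i % 31), education=educ,
                score_orientation=rng.normal(), score_immediate_recall=rng.normal(),
                score_delayed_recall=rng.normal(), score_fluency=rng.normal(),
                score_numeracy=rng.normal(),
            ))
    return recs
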