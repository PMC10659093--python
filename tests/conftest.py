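import numpy as np
import pandas as pd
import pytest

from gwical.cohort import (
    CDC_6MO_COLS,
    CDC_COLS,
    COHORT_COLUMNS,
    COMORBIDITIES,
    KANSAS_6MO_COLS,
    KANSAS_COLS,
    N_CDC,
    N_KANSAS,
    CohortParams,
)
from gwical.definitions import score_cohort
from gwical.synthetic import generate_cohort


def make_record(
    kansas=None,
    cdc=None,
    kansas_6mo=None,
    cdc_6mo=None,
    comorbidities=(),
    genotype="QQ",
    heard_alarms=False,
) -> pd.Series:
    """One veteran record; six-month flags default to True for endorsed symptoms."""
    kansas = np.zeros(N_KANSAS, dtype=int) if kansas is None else np.asarray(kansas)
    cdc = np.zeros(N_CDC, dtype=int) if cdc is None else np.asarray(cdc)
    kansas_6mo = kansas > 0 if kansas_6mo is None else np.asarray(kansas_6mo, bool)
    cdc_6mo = cdc > 0 if cdc_6mo is None else np.asarray(cdc_6mo, bool)
    rec = {col: 0 for col in COHORT_COLUMNS}
    rec.update(
        subject_id="S000000",
        genotype=genotype,
        heard_alarms=heard_alarms,
        age=40,
        sex=0,
        combat_scale=1,
        stratum_id=0,
        weight=1.0,
        sf12_mcs=50.0,
        sf12_pcs=50.0,
        research_latent=False,
        true_case=False,
    )
    rec.update(dict(zip(KANSAS_COLS, kansas)))
    rec.update(dict(zip(KANSAS_6MO_COLS, kansas_6mo)))
    rec.update(dict(zip(CDC_COLS, cdc)))
    rec.update(dict(zip(CDC_6MO_COLS, cdc_6mo)))
    for c in COMORBIDITIES:
        rec[c] = c in comorbidities
    return pd.Series(rec)


def random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Fully randomized records for property checks of the scoring rules."""
    frame = pd.DataFrame([make_record() for _ in range(n)])
    frame[KANSAS_COLS] = rng.integers(0, 4, (n, N_KANSAS))
    frame[KANSAS_6MO_COLS] = rng.random((n, N_KANSAS)) < 0.7
    frame[CDC_COLS] = rng.integers(0, 4, (n, N_CDC))
    frame[CDC_6MO_COLS] = rng.random((n, N_CDC)) < 0.7
    for c in COMORBIDITIES:
        frame[c] = rng.random(n) < 0.15
    frame["subject_id"] = [f"S{i:06d}" for i in range(n)]
    return frame


@pytest.fixture(scope="session")
def default_params():
    return CohortParams(seed=11)


@pytest.fixture(scope="session")
def cohort(default_params):
    return generate_cohort(default_params)


@pytest.fixture(scope="session")
def statuses(cohort):
    return score_cohort(cohort)
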