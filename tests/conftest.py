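import numpy as np
import pandas as pd
import pytest

from edscore import Cohort, default_profiles, generate_cohort
from edscore.schema import RECORD_COLUMNS


@pytest.fixture(scope="session")
def profiles():
    return {p.site_id: p for p in default_profiles()}


@pytest.fixture(scope="session")
def cohort_b_small(profiles):
    """Hospital-B-like cohort, small enough for fast unit tests."""
    return generate_cohort(profiles["B"], 6000, seed=42)


@pytest.fixture(scope="session")
def cohort_b_medium(profiles):
    """Hospital-B-like cohort large enough for score development."""
    return generate_cohort(profiles["B"], 20000, seed=7)


def make_cohort(df: pd.DataFrame, site_id: str = "T") -> Cohort:
    """Fill missing schema columns with benign defaults."""
    defaults = dict(
        age=40.0, sex="female", day_of_week="midweek", shift="day", ktas=3,
        consciousness="alert", route="direct", transport="other",
        pulse=80.0, sbp=120.0, dbp=80.0, resp_rate=16.0, spo2=98.0,
        temperature=36.8, doa=False, trauma=False, death_2day=False,
    )
    out = df.copy()
    for col in RECORD_COLUMNS:
        if col not in out.columns:
            out[col] = defaults.get(col, False)
    return Cohort(site_id=site_id, data=out[RECORD_COLUMNS].reset_index(drop=True))


@pytest.fixture
def tiny_cohort():
    """Ten hand-written records for enumeration oracles.

    Four records carry trauma=True, one of which (age 10) is also under 18,
    so sequential exclusion tallies must read age:1, doa:0, trauma:3 with six
    records retained.
    """
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        dict(
            age=[10, 18, 25, 40, 55, 60, 70, 80, 90, 33],
            trauma=[True, False, False, True, False, True, True, False, False, False],
            death_2day=[False, False, True, False, False, False, True, False, False, False],
        )
    )
    df["sbp"] = rng.normal(120, 10, len(df))
    return make_cohort(df)
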