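"""Synthetic cohort generation and the Cohort container.

Each record's outcome is drawn Bernoulli(prevalence); every predictor is then
drawn independently from its outcome class's conditional distribution —
truncated normal for continuous fields, categorical draw otherwise. A single
integer seed drives one named pseudo-random stream per cohort, so a fixed
(profile, n, seed) triple reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import SiteProfile
from .schema import (
    BOOLEAN_COLUMNS,
    CATEGORICAL_LEVELS,
    CONTINUOUS_BOUNDS,
    DEATH,
    OUTCOME,
    RECORD_COLUMNS,
    SURVIVOR,
)


@dataclass
class Cohort:
    """One hospital's patient-level data: a DataFrame with one row per visit."""

    site_id: str
    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing record columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_deaths(self) -> int:
        return int(self.data[OUTCOME].sum())

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for col in BOOLEAN_COLUMNS:
            out[col] = out[col].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_id: str, provenance: str = "") -> "Cohort":
        df = pd.read_csv(path)
        for col in BOOLEAN_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(bool)
        return cls(site_id=site_id, data=df, provenance=provenance or f"read from {path}")


def _truncnorm_draws(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(profile: SiteProfile, n: int, seed: int) -> Cohort:
    """Draw ``n`` triage records from a site profile.

    Parameters
    ----------
    profile : SiteProfile
        Generative parameters; validated before drawing.
    n : int
        Number of visits, at least 1.
    seed : int
        Seed for the cohort's private random stream.

    Returns
    -------
    Cohort
        Records in draw order. ``doa`` and ``trauma`` are false and ages are
        at least 18 unless the profile carries nonzero ``exclusion_rates``
        (used to demonstrate the exclusion flow).
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    profile.validate()
    rng = np.random.default_rng(seed)

    death = rng.random(n) < profile.prevalence
    masks = {SURVIVOR: ~death, DEATH: death}
    df = pd.DataFrame(index=np.arange(n))

    for var in profile.continuous:
        lo, hi = CONTINUOUS_BOUNDS[var]
        col = np.empty(n)
        for cls, mask in masks.items():
            m = int(mask.sum())
            if m:
                mean, sd = profile.continuous[var][cls]
                col[mask] = _truncnorm_draws(rng, mean, sd, lo, hi, m)
        df[var] = col

    for var in profile.categorical:
        levels = CATEGORICAL_LEVELS[var]
        col = np.empty(n, dtype=object)
        for cls, mask in masks.items():
            m = int(mask.sum())
            if m:
                probs = np.array([profile.categorical[var][cls][lv] for lv in levels])
                col[mask] = rng.choice(np.array(levels, dtype=object), size=m, p=probs)
        df[var] = col
        if var == "ktas":
            df[var] = df[var].astype(int)

    for flag in profile.comorbidity:
        col = np.zeros(n, dtype=bool)
        for cls, mask in masks.items():
            m = int(mask.sum())
            if m:
                col[mask] = rng.random(m) < profile.comorbidity[flag][cls]
        df[flag] = col

    ex = profile.exclusion_rates
    df["doa"] = rng.random(n) < ex.get("doa", 0.0)
    df["trauma"] = rng.random(n) < ex.get("trauma", 0.0)
    p_minor = ex.get("under_18", 0.0)
    if p_minor > 0:
        minor = rng.random(n) < p_minor
        df.loc[minor, "age"] = rng.uniform(1.0, 17.9, int(minor.sum()))
    df[OUTCOME] = death

    return Cohort(
        site_id=profile.site_id,
        data=df[RECORD_COLUMNS],
        provenance=f"generated: site={profile.site_id} n={n} seed={seed}",
    )
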