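"""Cohort selection, splitting and descriptive comparison.

Implements the study-flow bookkeeping around score generation: the exclusion
flow (adults only, no death-on-arrival/left-without-being-seen, no trauma),
the 70/30 development/test split, a baseline-demographics table comparing
survivors with 2-day-mortality cases (Welch t-test for continuous variables,
Pearson chi-square without continuity correction for categorical ones), and
standardized mean differences (SMD) for cross-hospital comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .schema import (
    CATEGORICAL_VARS,
    COMORBIDITY_VARS,
    CONTINUOUS_VARS,
    OUTCOME,
)


class CohortError(ValueError):
    pass


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Apply the selection-flow exclusions and tally removals per criterion.

    Records are removed for (in order, each record counted at its first
    matching criterion): age under 18; death on arrival / left without being
    seen; trauma. Raises if nothing survives the exclusions.
    """
    df = cohort.data
    under_age = df["age"] < 18
    doa = ~under_age & df["doa"].astype(bool)
    trauma = ~under_age & ~doa & df["trauma"].astype(bool)
    tally = {
        "age": int(under_age.sum()),
        "doa": int(doa.sum()),
        "trauma": int(trauma.sum()),
    }
    keep = ~(under_age | doa | trauma)
    if not keep.any():
        raise CohortError("all records excluded; cohort is empty after selection")
    retained = Cohort(
        site_id=cohort.site_id,
        data=df.loc[keep].reset_index(drop=True),
        provenance=cohort.provenance + f" | exclusions {tally}",
    )
    return retained, tally


def split_cohort(
    cohort: Cohort, dev_fraction: float = 0.7, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Random development/test partition of a cohort.

    The development cohort receives ``round(n * dev_fraction)`` records; the
    union of the two parts equals the input and their intersection is empty.
    Reproducible for a fixed seed.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise CohortError(f"dev_fraction must lie in (0, 1), got {dev_fraction}")
    n = len(cohort)
    n_dev = int(round(n * dev_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dev_idx, test_idx = np.sort(perm[:n_dev]), np.sort(perm[n_dev:])
    make = lambda idx, part: Cohort(
        site_id=cohort.site_id,
        data=cohort.data.iloc[idx].reset_index(drop=True),
        provenance=cohort.provenance + f" | {part} split f={dev_fraction} seed={seed}",
    )
    return make(dev_idx, "dev"), make(test_idx, "test")


def prevalence(cohort: Cohort) -> float:
    """Percent 2-day mortality, reported to two decimals (e.g. 0.51)."""
    if len(cohort) == 0:
        raise CohortError("empty cohort")
    return round(100.0 * cohort.n_deaths / len(cohort), 2)


# -- standardized mean differences ----------------------------------------


def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """|m1 - m2| / sqrt((s1^2 + s2^2) / 2)."""
    pooled = (sd1**2 + sd2**2) / 2.0
    if pooled == 0:
        if mean1 != mean2:
            raise CohortError("zero pooled variance with unequal means")
        return 0.0
    return abs(mean1 - mean2) / np.sqrt(pooled)


def smd_binary(p1: float, p2: float) -> float:
    """|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)."""
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0:
        if p1 != p2:
            raise CohortError("zero pooled variance with unequal proportions")
        return 0.0
    return abs(p1 - p2) / np.sqrt(pooled)


def smd_categorical(p1: np.ndarray, p2: np.ndarray) -> float:
    """Mahalanobis-style SMD over K-category proportion vectors.

    Drops the last category, forms the average multinomial covariance
    S = (S1 + S2)/2 and returns sqrt(d' S^+ d) for d = p1 - p2 (pseudo-inverse
    guards against degenerate categories).
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    if p1.shape != p2.shape:
        raise CohortError("proportion vectors differ in length")
    d = (p1 - p2)[:-1]
    q1, q2 = p1[:-1], p2[:-1]
    s = ((np.diag(q1) - np.outer(q1, q1)) + (np.diag(q2) - np.outer(q2, q2))) / 2.0
    return float(np.sqrt(d @ np.linalg.pinv(s) @ d))


def smd(group1, group2, kind: str | None = None) -> float:
    """Standardized mean difference between two group summaries.

    ``kind`` is one of ``"continuous"`` (summaries are ``(mean, sd)``),
    ``"binary"`` (scalar proportions) or ``"categorical"`` (proportion
    vectors). When omitted it is inferred from the argument type: scalar →
    binary, tuple → continuous, list/array → categorical.
    """
    if kind is None:
        if np.isscalar(group1):
            kind = "binary"
        elif isinstance(group1, tuple):
            kind = "continuous"
        else:
            kind = "categorical"
    if kind == "binary":
        return smd_binary(float(group1), float(group2))
    if kind == "continuous":
        (m1, s1), (m2, s2) = group1, group2
        return smd_continuous(m1, s1, m2, s2)
    if kind == "categorical":
        return smd_categorical(np.asarray(group1, float), np.asarray(group2, float))
    raise CohortError(f"unknown SMD kind {kind!r}")


# -- demographics table ----------------------------------------------------


@dataclass
class DemographicsReport:
    """Class-stratified baseline table for one cohort.

    ``table`` has one row per variable (continuous) or per category
    (categorical/comorbidity) with survivor and death summaries and the
    comparison p-value attached to the variable's first row.
    """

    site_id: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        lines = [
            f"# Baseline demographics — hospital {self.site_id}",
            "",
            "| Variable | Category | Survivors | 2-day mortality | p-value |",
            "|---|---|---|---|---|",
        ]
        for _, row in self.table.iterrows():
            p = "" if pd.isna(row["p_value"]) else (
                "<0.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
            )
            lines.append(
                f"| {row['variable']} | {row['category'] or ''} "
                f"| {row['survivor']} | {row['death']} | {p} |"
            )
        return "\n".join(lines) + "\n"


def demographics_table(cohort: Cohort) -> DemographicsReport:
    """Baseline table with per-variable class comparison tests.

    Continuous variables: class mean ± SD and Welch's two-sample t-test.
    Categorical variables and comorbidity flags: class counts (percent) and
    the Pearson chi-square test without continuity correction.
    """
    df = cohort.data
    dead = df[OUTCOME].astype(bool)
    if dead.all() or (~dead).all():
        raise CohortError("both outcome classes must be present")
    surv_df, death_df = df[~dead], df[dead]
    rows = []

    for var in CONTINUOUS_VARS:
        x, y = surv_df[var], death_df[var]
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        rows.append(
            dict(
                variable=var,
                category=None,
                survivor=f"{x.mean():.1f} ± {x.std(ddof=1):.1f}",
                death=f"{y.mean():.1f} ± {y.std(ddof=1):.1f}",
                p_value=p,
            )
        )

    for var in CATEGORICAL_VARS + COMORBIDITY_VARS:
        if var in COMORBIDITY_VARS:
            levels = [True, False]
            fmt = lambda lv: "present" if lv else "absent"
        else:
            levels = sorted(df[var].unique(), key=str)
            fmt = str
        counts = pd.crosstab(df[var], dead).reindex(levels, fill_value=0)
        table = counts.to_numpy()
        nonempty = table.sum(axis=1) > 0
        if nonempty.sum() < 2 or table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            p = np.nan
        else:
            chi = stats.chi2_contingency(table[nonempty], correction=False)
            p = 1.0 if chi.statistic == 0 else float(chi.pvalue)
        n_surv, n_death = (~dead).sum(), dead.sum()
        first = True
        for lv in levels:
            cs = int(counts.loc[lv, False]) if False in counts.columns else 0
            cd = int(counts.loc[lv, True]) if True in counts.columns else 0
            if var in COMORBIDITY_VARS and lv is False:
                continue  # report only flag presence, as in baseline tables
            rows.append(
                dict(
                    variable=var,
                    category=fmt(lv),
                    survivor=f"{cs} ({100.0 * cs / n_surv:.1f}%)",
                    death=f"{cd} ({100.0 * cd / n_death:.1f}%)",
                    p_value=p if first else np.nan,
                )
            )
            first = False

    return DemographicsReport(site_id=cohort.site_id, table=pd.DataFrame(rows))


def pairwise_smd(cohort_a: Cohort, cohort_b: Cohort) -> pd.DataFrame:
    """Per-variable SMD between two cohorts (marginal distributions)."""
    rows = []
    for var in CONTINUOUS_VARS:
        xa, xb = cohort_a.data[var], cohort_b.data[var]
        rows.append(
            dict(variable=var, smd=smd_continuous(xa.mean(), xa.std(ddof=1), xb.mean(), xb.std(ddof=1)))
        )
    for var in CATEGORICAL_VARS:
        levels = sorted(set(cohort_a.data[var]) | set(cohort_b.data[var]), key=str)
        pa = cohort_a.data[var].value_counts(normalize=True).reindex(levels, fill_value=0.0).to_numpy()
        pb = cohort_b.data[var].value_counts(normalize=True).reindex(levels, fill_value=0.0).to_numpy()
        rows.append(dict(variable=var, smd=smd_categorical(pa, pb)))
    for var in COMORBIDITY_VARS:
        rows.append(
            dict(variable=var, smd=smd_binary(cohort_a.data[var].mean(), cohort_b.data[var].mean()))
        )
    return pd.DataFrame(rows)
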