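"""Interpretable point-based score generation (six-module procedure).

The score generator converts a development cohort into an integer clinical
scorecard in six steps:

1. rank candidate variables with a seeded random forest (permutation
   importance on a held-out fold);
2. categorise continuous variables, either from development-data quantiles
   or from an explicit clinically chosen cutoff scheme;
3. fit a logistic regression of the outcome on the category indicators and
   turn its coefficients into nonnegative integer points (negative
   coefficients clamped to zero, all coefficients divided by the smallest
   positive one, rescaled so the maximum achievable total is 100, rounded
   half away from zero);
4. choose the number of variables from a parsimony curve of validation AUROC
   versus model size (or force a fixed k);
5. optionally override cutoffs/variables with clinical domain knowledge;
6. evaluate the resulting score on a separate test set (see
   :mod:`edscore.validation`).

Published scorecards for the three study hospitals and their weighted overall
combination ship as fixtures via :func:`paper_score_tables`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .cohort import Cohort
from .schema import (
    CATEGORICAL_LEVELS,
    COMORBIDITY_VARS,
    CONTINUOUS_VARS,
    OUTCOME,
    TRIAGE_VARS,
)

logger = logging.getLogger(__name__)

# Clinically chosen cutoffs for the eight scorecard variables.
CLINICAL_CUTS: dict[str, list[float]] = {
    "age": [60.0, 80.0],
    "pulse": [50.0, 100.0],
    "resp_rate": [24.0],
    "temperature": [36.0],
    "sbp": [90.0],
    "dbp": [60.0],
    "spo2": [90.0, 95.0],
}

# The eight variables of the published scorecards.
CLINICAL_SCORE_VARS: list[str] = [
    "age",
    "pulse",
    "resp_rate",
    "temperature",
    "sbp",
    "dbp",
    "spo2",
    "consciousness",
]


class ScoreError(ValueError):
    pass


class ScoreFitError(ScoreError):
    pass


def _round_half_away(x) -> np.ndarray:
    x = np.asarray(x, float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def _fmt(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else f"{c:g}"


def interval_labels(cuts: list[float]) -> list[str]:
    """Left-closed/right-open bin labels for interior cut points.

    ``[60, 80]`` → ``["<60", "60-80", ">=80"]``; a value equal to a cut point
    falls in the bin to its right (age 60 scores as "60-80").
    """
    if not cuts:
        raise ScoreError("at least one cut point required")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ScoreError(f"cut points must be strictly increasing, got {cuts}")
    labels = [f"<{_fmt(cuts[0])}"]
    labels += [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(cuts, cuts[1:])]
    labels.append(f">={_fmt(cuts[-1])}")
    return labels


# -- cutoff scheme ---------------------------------------------------------


@dataclass
class CutoffScheme:
    """Categorisation plan: cut points per continuous variable, category
    levels per categorical variable, and one reference category per variable.

    ``unusable`` lists variables that collapsed to a single category under
    quantile binning (e.g. constants) and must not enter the score.
    """

    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)
    unusable: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for var, spec in self.continuous.items():
            labels = interval_labels(spec["cuts"])  # raises if not increasing
            ref = spec.get("reference")
            if ref is not None and ref not in labels:
                raise ScoreError(f"{var!r}: reference {ref!r} not among {labels}")
        for var, spec in self.categorical.items():
            levels = [str(lv) for lv in spec["levels"]]
            if len(levels) < 2:
                raise ScoreError(f"{var!r}: needs at least 2 categories")
            ref = spec.get("reference")
            if ref is not None and str(ref) not in levels:
                raise ScoreError(f"{var!r}: reference {ref!r} not among {levels}")

    def variables(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)

    def labels_for(self, var: str) -> list[str]:
        if var in self.continuous:
            return interval_labels(self.continuous[var]["cuts"])
        return [str(lv) for lv in self.categorical[var]["levels"]]

    def reference_for(self, var: str) -> str:
        spec = self.continuous.get(var) or self.categorical[var]
        ref = spec.get("reference")
        if ref is None:
            raise ScoreError(f"{var!r}: no reference category set")
        return str(ref)

    def to_dict(self) -> dict:
        return {
            "continuous": {
                v: {"cuts": [float(c) for c in s["cuts"]], "reference": s.get("reference")}
                for v, s in self.continuous.items()
            },
            "categorical": {
                v: {"levels": [str(x) for x in s["levels"]], "reference": s.get("reference")}
                for v, s in self.categorical.items()
            },
            "unusable": list(self.unusable),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffScheme":
        scheme = cls(
            continuous={v: dict(s) for v, s in d.get("continuous", {}).items()},
            categorical={v: dict(s) for v, s in d.get("categorical", {}).items()},
            unusable=list(d.get("unusable", [])),
        )
        scheme.validate()
        return scheme

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CutoffScheme":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def clinical_cutoff_scheme(variables: list[str] | None = None) -> CutoffScheme:
    """The domain-knowledge cutoff scheme of the published scorecards.

    References are the physiologically normal bins (zero-point rows):
    age < 60, pulse 50–100, respiration < 24, temperature ≥ 36 °C,
    SBP ≥ 90, DBP ≥ 60, SpO2 ≥ 95, alert consciousness.
    """
    refs = {
        "age": "<60",
        "pulse": "50-100",
        "resp_rate": "<24",
        "temperature": ">=36",
        "sbp": ">=90",
        "dbp": ">=60",
        "spo2": ">=95",
    }
    # lowest-risk reference levels for the categorical triage variables
    cat_refs = {
        "consciousness": "alert",
        "ktas": "5",
        "route": "direct",
        "transport": "other",
        "sex": "female",
        "day_of_week": "midweek",
        "shift": "day",
    }
    variables = variables or CLINICAL_SCORE_VARS
    scheme = CutoffScheme()
    for var in variables:
        if var in CLINICAL_CUTS:
            scheme.continuous[var] = {"cuts": list(CLINICAL_CUTS[var]), "reference": refs[var]}
        elif var in CATEGORICAL_LEVELS:
            ref = cat_refs.get(var, str(CATEGORICAL_LEVELS[var][0]))
            scheme.categorical[var] = {"levels": list(CATEGORICAL_LEVELS[var]), "reference": ref}
        elif var in COMORBIDITY_VARS:
            scheme.categorical[var] = {"levels": [False, True], "reference": "False"}
        else:
            raise ScoreError(f"no clinical cutoffs defined for {var!r}")
    scheme.validate()
    return scheme


# -- score table -----------------------------------------------------------


@dataclass
class ScoreTable:
    """Integer scorecard: variable → category → nonnegative points.

    ``variables`` maps each variable name to a spec dict with ``type``
    ("continuous"/"categorical"), ``cuts`` (continuous only), ``points``
    (label → int) and ``reference`` (label with 0 points).
    """

    site_id: str
    variables: dict[str, dict]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, spec in self.variables.items():
            for label, pts in spec["points"].items():
                if int(pts) != pts or pts < 0:
                    raise ScoreError(f"{var!r}/{label!r}: points must be nonnegative integers")
            ref = spec.get("reference")
            if ref is not None and spec["points"].get(ref, 0) != 0:
                raise ScoreError(f"{var!r}: reference category {ref!r} must score 0")

    @property
    def max_total(self) -> int:
        return int(sum(max(spec["points"].values()) for spec in self.variables.values()))

    def points(self, var: str, category) -> int:
        spec = self.variables[var]
        key = str(category)
        if key not in spec["points"]:
            raise ScoreError(f"variable {var!r}: unmapped category {category!r}")
        return int(spec["points"][key])

    def category_of(self, var: str, value) -> str:
        """Map a raw value to its category label (continuous bins are
        left-closed/right-open)."""
        spec = self.variables[var]
        if spec["type"] == "continuous":
            v = float(value)
            if np.isnan(v):
                raise ScoreError(f"variable {var!r}: value is NaN")
            cuts = spec["cuts"]
            labels = interval_labels(cuts)
            return labels[int(np.searchsorted(cuts, v, side="right"))]
        return str(value)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "variables": {
                v: {
                    "type": s["type"],
                    **({"cuts": [float(c) for c in s["cuts"]]} if s["type"] == "continuous" else {}),
                    "points": {k: int(p) for k, p in s["points"].items()},
                    "reference": s.get("reference"),
                }
                for v, s in self.variables.items()
            },
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreTable":
        return cls(site_id=d["site_id"], variables=d["variables"], metadata=d.get("metadata", {}))

    @classmethod
    def from_json(cls, path) -> "ScoreTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_markdown(self) -> str:
        lines = [
            f"# Scorecard — {self.site_id} (max total {self.max_total})",
            "",
            "| Variable | Category | Points |",
            "|---|---|---|",
        ]
        for var, spec in self.variables.items():
            order = (
                interval_labels(spec["cuts"])
                if spec["type"] == "continuous"
                else list(spec["points"])
            )
            for label in order:
                lines.append(f"| {var} | {label} | {spec['points'][label]} |")
        return "\n".join(lines) + "\n"


# -- module 1: variable ranking --------------------------------------------


@dataclass
class RankedVariables:
    """Variables sorted by importance, descending (ties broken by name)."""

    items: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.items]
        if len(set(names)) != len(names):
            raise ScoreError("duplicate variable names in ranking")
        imps = [i for _, i in self.items]
        if any(b > a for a, b in zip(imps, imps[1:])):
            raise ScoreError("importances must be nonincreasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def _encode_design(df: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """One numeric column per variable (ordinal codes for categoricals)."""
    out = {}
    for var in variables:
        if var in CATEGORICAL_LEVELS:
            out[var] = pd.Categorical(
                df[var], categories=CATEGORICAL_LEVELS[var]
            ).codes.astype(float)
        else:
            out[var] = pd.to_numeric(df[var]).astype(float)
    return pd.DataFrame(out, index=df.index)


def rank_variables(
    dev: Cohort,
    seed: int = 0,
    candidates: list[str] | None = None,
    n_estimators: int = 500,
    holdout_fraction: float = 0.25,
    n_repeats: int = 5,
) -> RankedVariables:
    """Rank candidate predictors by random-forest permutation importance.

    A forest of ``n_estimators`` seeded trees is fitted on a stratified
    training fold; permutation importance (AUROC loss) is measured on the
    held-out fold so the ranking is robust to the ordinal encoding of
    categoricals. Ties are broken by variable-name order.
    """
    candidates = list(candidates or TRIAGE_VARS)
    if len(candidates) < 2:
        raise ScoreError("need at least 2 candidate variables")
    y = dev.data[OUTCOME].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ScoreError("both outcome classes must be present")
    x = _encode_design(dev.data, candidates)
    x_fit, x_hold, y_fit, y_hold = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(x_fit, y_fit)
    imp = permutation_importance(
        forest, x_hold, y_hold, scoring="roc_auc", n_repeats=n_repeats, random_state=seed
    )
    pairs = sorted(
        zip(candidates, imp.importances_mean), key=lambda p: (-p[1], p[0])
    )
    return RankedVariables(items=[(n, float(i)) for n, i in pairs])


# -- module 2/5: categorisation --------------------------------------------

_QUANTILES = (5, 20, 80, 95)
_MIN_OCCUPANCY = 0.01


def _auto_cuts(values: np.ndarray) -> list[float]:
    """Quantile cut points (5/20/80/95th percentiles), then merge adjacent
    bins holding < 1% of the data."""
    cuts = sorted(set(float(np.percentile(values, q)) for q in _QUANTILES))
    while cuts:
        labels_edges = [-np.inf] + cuts + [np.inf]
        counts, _ = np.histogram(values, bins=labels_edges)
        frac = counts / len(values)
        if (frac >= _MIN_OCCUPANCY).all():
            break
        # drop the cut bounding the sparsest bin (merging it with a neighbour)
        i = int(np.argmin(frac))
        drop = i if i < len(cuts) else len(cuts) - 1
        cuts.pop(drop)
    return cuts


def categorize(
    dev: Cohort | pd.DataFrame,
    variables: list[str],
    scheme: CutoffScheme | str = "auto-quantile",
) -> tuple[pd.DataFrame, CutoffScheme]:
    """Map every value to its category; derive cut points if requested.

    With ``scheme="auto-quantile"`` continuous cut points are placed at the
    5th/20th/80th/95th development percentiles and sparse bins (< 1%
    occupancy) are merged; references default to the most frequent category.
    An explicit :class:`CutoffScheme` is applied verbatim. Variables whose
    quantile bins collapse to a single category are flagged unusable and
    excluded from the returned design.
    """
    df = dev.data if isinstance(dev, Cohort) else dev
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ScoreError(f"variables not in records: {missing}")

    if isinstance(scheme, str):
        if scheme != "auto-quantile":
            raise ScoreError(f"unknown scheme {scheme!r}")
        resolved = CutoffScheme()
        for var in variables:
            if var in CONTINUOUS_VARS:
                values = pd.to_numeric(df[var]).to_numpy(float)
                cuts = _auto_cuts(values)
                if not cuts:
                    logger.warning("variable %r is constant under quantile binning; unusable", var)
                    resolved.unusable.append(var)
                    continue
                resolved.continuous[var] = {"cuts": cuts, "reference": None}
            else:
                schema_levels = CATEGORICAL_LEVELS.get(var, sorted(df[var].unique(), key=str))
                levels = [lv for lv in schema_levels if (df[var] == lv).any()]
                if len(levels) < 2:
                    logger.warning("variable %r has a single observed category; unusable", var)
                    resolved.unusable.append(var)
                    continue
                resolved.categorical[var] = {"levels": levels, "reference": None}
    else:
        scheme.validate()
        resolved = CutoffScheme(
            continuous={v: dict(s) for v, s in scheme.continuous.items() if v in variables},
            categorical={v: dict(s) for v, s in scheme.categorical.items() if v in variables},
            unusable=list(scheme.unusable),
        )
        uncovered = [
            v for v in variables
            if v not in resolved.continuous and v not in resolved.categorical
        ]
        if uncovered:
            raise ScoreError(f"scheme does not cover variables: {uncovered}")

    design = {}
    for var in resolved.continuous:
        cuts = resolved.continuous[var]["cuts"]
        labels = interval_labels(cuts)
        values = pd.to_numeric(df[var]).to_numpy(float)
        if np.isnan(values).any():
            raise ScoreError(f"variable {var!r}: NaN values cannot be categorised")
        idx = np.searchsorted(cuts, values, side="right")
        design[var] = pd.Series(np.array(labels, dtype=object)[idx], index=df.index)
        if resolved.continuous[var].get("reference") is None:
            counts = design[var].value_counts()
            resolved.continuous[var]["reference"] = str(counts.idxmax())
    for var in resolved.categorical:
        levels = [str(lv) for lv in resolved.categorical[var]["levels"]]
        col = df[var].astype(str)
        bad = ~col.isin(levels)
        if bad.any():
            raise ScoreError(
                f"variable {var!r}: values outside scheme categories: "
                f"{sorted(col[bad].unique())}"
            )
        design[var] = col
        if resolved.categorical[var].get("reference") is None:
            resolved.categorical[var]["reference"] = str(col.value_counts().idxmax())

    return pd.DataFrame(design, index=df.index), resolved


# -- module 3: coefficients -> points --------------------------------------


def points_from_coefficients(
    coef: dict[tuple[str, str], float], max_total: int = 100
) -> dict[tuple[str, str], int]:
    """Map logistic coefficients to integer points.

    ``coef`` maps (variable, category) to the fitted coefficient of that
    category's indicator (reference categories omitted). Negative
    coefficients are clamped to 0, all are divided by the smallest positive
    coefficient, rescaled so the maximum achievable total equals
    ``max_total`` and rounded half away from zero. Invariant under positive
    scaling of all coefficients.
    """
    names = list(coef)
    beta = np.clip(np.array([coef[n] for n in names], float), 0.0, None)
    if (beta > 0).any():
        # dividing by the smallest positive coefficient cancels under the
        # max-total rescale, so points are computed directly on clamped betas
        per_var_max: dict[str, float] = {}
        for (var, _), b in zip(names, beta):
            per_var_max[var] = max(per_var_max.get(var, 0.0), b)
        scale = max_total / sum(per_var_max.values())
        pts = _round_half_away(beta * scale)
    else:
        pts = np.zeros(len(beta), dtype=int)
    return {n: int(p) for n, p in zip(names, pts)}


def fit_points(
    design: pd.DataFrame,
    outcome: pd.Series,
    scheme: CutoffScheme,
    site_id: str = "",
    max_total: int = 100,
) -> ScoreTable:
    """Fit logistic regression on category indicators and emit a scorecard.

    Coefficients are clamped at zero from below, divided by the smallest
    positive coefficient, rescaled so the maximum achievable total equals
    ``max_total``, and rounded half away from zero. The reference category of
    every variable scores 0 by construction.
    """
    variables = [v for v in scheme.variables() if v in design.columns]
    if not variables:
        raise ScoreFitError("no usable variables in design")
    y = outcome.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ScoreFitError("both outcome classes must be present")

    columns, col_names, empty = [], [], []
    for var in variables:
        ref = scheme.reference_for(var)
        for label in scheme.labels_for(var):
            if label == ref:
                continue
            col = (design[var] == label).to_numpy(float)
            if col.sum() == 0:  # unobserved category scores 0 by convention
                empty.append((var, label))
                continue
            columns.append(col)
            col_names.append((var, label))
    if empty:
        logger.debug("categories unobserved in development data score 0: %s", empty)
    if not columns:
        raise ScoreFitError("no non-reference categories observed in development data")
    x = sm.add_constant(np.column_stack(columns), has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception:
            try:  # near-singular Hessian or separation: quasi-Newton fallback
                fit = sm.Logit(y, x).fit(disp=0, maxiter=500, method="bfgs")
            except Exception as err:
                raise ScoreFitError(
                    f"logistic fit failed ({err}); merge sparse categories and retry"
                ) from err
    if not np.isfinite(fit.params).all():
        raise ScoreFitError("logistic fit diverged; merge sparse categories and retry")

    coef = dict(zip(col_names, fit.params[1:]))
    fitted = points_from_coefficients(coef, max_total=max_total)
    table_vars: dict[str, dict] = {}
    for var in variables:
        ref = scheme.reference_for(var)
        pts = {label: fitted.get((var, label), 0) for label in scheme.labels_for(var)}
        pts[ref] = 0
        spec: dict = {"type": "continuous" if var in scheme.continuous else "categorical",
                      "points": pts, "reference": ref}
        if var in scheme.continuous:
            spec["cuts"] = [float(c) for c in scheme.continuous[var]["cuts"]]
        table_vars[var] = spec

    return ScoreTable(
        site_id=site_id,
        variables=table_vars,
        metadata={"n_dev": int(len(design)), "max_total_target": max_total},
    )


# -- module 4: parsimony ----------------------------------------------------


@dataclass
class ParsimonyCurve:
    """Validation AUROC as a function of the number of top-ranked variables."""

    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        if ks != sorted(set(ks)) or (ks and ks[0] < 1):
            raise ScoreError("k must be strictly increasing from 1")

    def select(self, tol: float = 0.005, forced_k: int | None = None) -> int:
        """Smallest k whose AUROC is within ``tol`` (relative) of the best,
        unless ``forced_k`` overrides the choice."""
        if forced_k is not None:
            return int(forced_k)
        finite = [(k, a) for k, a in self.points if np.isfinite(a)]
        if not finite:
            raise ScoreError("no successful fits on the parsimony curve")
        best = max(a for _, a in finite)
        for k, a in finite:
            if a >= (1.0 - tol) * best:
                return k
        return finite[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["k", "auroc"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame()
        ax.plot(frame["k"], frame["auroc"], marker="o")
        ax.set_xlabel("number of top-ranked variables")
        ax.set_ylabel("validation AUROC")
        return ax


def parsimony_curve(
    ranked: RankedVariables,
    dev: Cohort,
    val: Cohort,
    k_max: int,
    scheme: CutoffScheme | str = "auto-quantile",
) -> ParsimonyCurve:
    """AUROC of a top-k score on the validation cohort, for k = 1..k_max.

    Fit failures for a given k are recorded as NaN gaps rather than aborting
    the curve.
    """
    from .validation import auroc as _auroc

    if k_max > len(ranked.items):
        raise ScoreError(f"k_max={k_max} exceeds {len(ranked.items)} ranked variables")
    out = []
    y_val = val.data[OUTCOME].astype(int).to_numpy()
    for k in range(1, k_max + 1):
        variables = ranked.top(k)
        try:
            design, resolved = categorize(dev, variables, scheme)
            table = fit_points(design, dev.data[OUTCOME], resolved, site_id=dev.site_id)
            totals = apply_score(val.data, table)
            out.append((k, float(_auroc(totals, y_val))))
        except ScoreError as err:
            logger.warning("parsimony k=%d failed: %s", k, err)
            out.append((k, float("nan")))
    return ParsimonyCurve(points=out)


# -- module 6 helper: score application -------------------------------------


def apply_score(records, table: ScoreTable):
    """Total integer score for one record (mapping) or a DataFrame of records.

    A variable absent from a record scores 0 (reference) with a logged
    warning; an unmapped category value raises naming the variable.
    """
    single = isinstance(records, dict)
    df = pd.DataFrame([records]) if single else records
    totals = np.zeros(len(df), dtype=int)
    for var, spec in table.variables.items():
        if var not in df.columns:
            logger.warning("variable %r missing from records; scoring as reference (0)", var)
            continue
        if spec["type"] == "continuous":
            values = pd.to_numeric(df[var]).to_numpy(float)
            if np.isnan(values).any():
                raise ScoreError(f"variable {var!r}: NaN values cannot be scored")
            cuts = spec["cuts"]
            labels = interval_labels(cuts)
            pts = np.array([spec["points"][lb] for lb in labels], dtype=int)
            totals += pts[np.searchsorted(cuts, values, side="right")]
        else:
            mapping = {str(k): int(v) for k, v in spec["points"].items()}
            col = df[var].astype(str)
            bad = ~col.isin(mapping)
            if bad.any():
                raise ScoreError(
                    f"variable {var!r}: unmapped category values "
                    f"{sorted(col[bad].unique())}"
                )
            totals += col.map(mapping).to_numpy(int)
    return int(totals[0]) if single else totals


# -- published fixtures ------------------------------------------------------

_PAPER_POINTS: dict[str, dict[str, list[int]]] = {
    # variable -> label -> [A, B, C, overall]
    "age": {"<60": [0, 0, 0, 0], "60-80": [4, 13, 11, 8], ">=80": [4, 20, 12, 11]},
    "pulse": {"<50": [4, 7, 2, 5], "50-100": [0, 0, 0, 0], ">=100": [9, 7, 2, 7]},
    "resp_rate": {"<24": [0, 0, 0, 0], ">=24": [13, 7, 6, 10]},
    "temperature": {"<36": [17, 7, 10, 12], ">=36": [0, 0, 0, 0]},
    "sbp": {"<90": [9, 7, 14, 9], ">=90": [0, 0, 0, 0]},
    "dbp": {"<60": [4, 7, 1, 5], ">=60": [0, 0, 0, 0]},
    "spo2": {"<90": [17, 13, 14, 15], "90-95": [4, 7, 5, 5], ">=95": [0, 0, 0, 0]},
    "consciousness": {
        "alert": [0, 0, 0, 0],
        "verbal": [9, 13, 12, 11],
        "painful": [13, 20, 19, 17],
        "unconscious": [13, 33, 40, 24],
    },
}


def paper_score_tables() -> dict[str, ScoreTable]:
    """The published 2-day-mortality scorecards, keyed "A", "B", "C",
    "overall".

    Eight variables with the clinical cutoff scheme. The temperature
    threshold is recorded as 36 °C; the source table prints it as 24 °C,
    which is physiologically impossible and inconsistent with the risk
    direction (low temperature scores points) — noted in metadata.
    """
    scheme = clinical_cutoff_scheme()
    tables = {}
    for i, site in enumerate(["A", "B", "C", "overall"]):
        variables = {}
        for var, rows in _PAPER_POINTS.items():
            spec: dict = {
                "type": "continuous" if var in CLINICAL_CUTS else "categorical",
                "points": {label: pts[i] for label, pts in rows.items()},
                "reference": scheme.reference_for(var),
            }
            if var in CLINICAL_CUTS:
                spec["cuts"] = list(CLINICAL_CUTS[var])
            variables[var] = spec
        tables[site] = ScoreTable(
            site_id=site,
            variables=variables,
            metadata={
                "source": "published scorecard fixture",
                "temperature_cutoff_note": (
                    "source prints '< 24 / >= 24' degC; 36 degC assumed "
                    "(typo; risk direction requires a low-temperature bin)"
                ),
                **({"weights": {"A": 0.472, "B": 0.410, "C": 0.116}} if site == "overall" else {}),
            },
        )
    return tables
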