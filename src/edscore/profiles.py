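"""Per-hospital generative parameters for synthetic triage cohorts.

A :class:`SiteProfile` stores, for one hospital, the 2-day-mortality
prevalence and the class-conditional distribution of every record field:
truncated-normal (mean, sd) per outcome class for the continuous vitals and
age, category probability vectors for the categorical triage variables, and a
per-class Bernoulli probability for every comorbidity flag. Predictors are
modelled as conditionally independent given the outcome class — the simplest
generative model consistent with published marginal class-conditional
summaries, since joint structure is rarely reported.

``default_profiles`` ships the baseline-demographics parameters of three
Korean tertiary-hospital ED cohorts (labelled A, B, C) so that every
downstream stage runs without access to hospital data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .schema import (
    CATEGORICAL_LEVELS,
    CATEGORICAL_VARS,
    COMORBIDITY_VARS,
    CONTINUOUS_BOUNDS,
    CONTINUOUS_VARS,
    CLASSES,
    DEATH,
    SURVIVOR,
)

_PROB_TOL = 1e-9


class ProfileError(ValueError):
    """Raised when a profile violates its invariants."""


@dataclass
class SiteProfile:
    """Generative parameters for one hospital's ED population.

    Parameters
    ----------
    site_id : str
        Hospital label.
    prevalence : float
        Probability of 2-day mortality, in (0, 1).
    continuous : dict
        ``{variable: {class: (mean, sd)}}`` for each continuous variable,
        classes ``"survivor"`` and ``"death"``. Draws are truncated to
        :data:`edscore.schema.CONTINUOUS_BOUNDS`.
    categorical : dict
        ``{variable: {class: {category: probability}}}``. Vectors are
        renormalised to sum to one at validation (printed percentages
        occasionally sum to 100.1 due to rounding).
    comorbidity : dict
        ``{flag: {class: probability}}`` of the flag being present.
    exclusion_rates : dict
        Optional rates for demonstration of the exclusion flow:
        ``{"doa": p, "trauma": p, "under_18": p}``. All zero by default —
        cohorts are generated post-exclusion.
    """

    site_id: str
    prevalence: float
    continuous: dict[str, dict[str, tuple[float, float]]]
    categorical: dict[str, dict[str, dict]]
    comorbidity: dict[str, dict[str, float]]
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: {"doa": 0.0, "trauma": 0.0, "under_18": 0.0}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ProfileError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        for var, per_class in self.continuous.items():
            if var not in CONTINUOUS_BOUNDS:
                raise ProfileError(f"unknown continuous variable {var!r}")
            lo, hi = CONTINUOUS_BOUNDS[var]
            if not lo < hi:
                raise ProfileError(f"bounds for {var!r} are not ordered")
            for cls in CLASSES:
                mean, sd = per_class[cls]
                if sd <= 0:
                    raise ProfileError(f"{var!r}/{cls}: sd must be positive, got {sd}")
        for var, per_class in self.categorical.items():
            if var not in CATEGORICAL_LEVELS:
                raise ProfileError(f"unknown categorical variable {var!r}")
            levels = CATEGORICAL_LEVELS[var]
            for cls in CLASSES:
                probs = per_class[cls]
                if set(probs) != set(levels):
                    raise ProfileError(
                        f"{var!r}/{cls}: categories {sorted(map(str, probs))} do not "
                        f"match schema levels {sorted(map(str, levels))}"
                    )
                total = float(sum(probs.values()))
                if total <= 0:
                    raise ProfileError(f"{var!r}/{cls}: probabilities sum to zero")
                if abs(total - 1.0) > _PROB_TOL:
                    # printed percentages can sum to 100.1; renormalise in place
                    for k in probs:
                        probs[k] = probs[k] / total
        for flag, per_class in self.comorbidity.items():
            if flag not in COMORBIDITY_VARS:
                raise ProfileError(f"unknown comorbidity flag {flag!r}")
            for cls in CLASSES:
                p = per_class[cls]
                if not 0.0 <= p <= 1.0:
                    raise ProfileError(f"{flag!r}/{cls}: probability {p} outside [0, 1]")
        for key, p in self.exclusion_rates.items():
            if key not in ("doa", "trauma", "under_18"):
                raise ProfileError(f"unknown exclusion rate {key!r}")
            if not 0.0 <= p < 1.0:
                raise ProfileError(f"exclusion rate {key!r}={p} outside [0, 1)")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "prevalence": float(self.prevalence),
            "continuous": {
                v: {c: [float(m), float(s)] for c, (m, s) in per.items()}
                for v, per in self.continuous.items()
            },
            "categorical": {
                v: {c: {str(k): float(p) for k, p in d.items()} for c, d in per.items()}
                for v, per in self.categorical.items()
            },
            "comorbidity": {
                v: {c: float(p) for c, p in per.items()}
                for v, per in self.comorbidity.items()
            },
            "exclusion_rates": {k: float(p) for k, p in self.exclusion_rates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteProfile":
        categorical = {}
        for var, per in d["categorical"].items():
            levels = {str(lv): lv for lv in CATEGORICAL_LEVELS[var]}
            categorical[var] = {
                c: {levels[k]: float(p) for k, p in probs.items()}
                for c, probs in per.items()
            }
        return cls(
            site_id=d["site_id"],
            prevalence=float(d["prevalence"]),
            continuous={
                v: {c: (float(m), float(s)) for c, (m, s) in per.items()}
                for v, per in d["continuous"].items()
            },
            categorical=categorical,
            comorbidity={
                v: {c: float(p) for c, p in per.items()}
                for v, per in d["comorbidity"].items()
            },
            exclusion_rates=dict(d.get("exclusion_rates", {"doa": 0.0, "trauma": 0.0, "under_18": 0.0})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SiteProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _pct(d: dict) -> dict:
    """Percentages -> probabilities."""
    return {k: v / 100.0 for k, v in d.items()}


def _site(
    site_id: str,
    deaths: int,
    total: int,
    cont: dict[str, tuple[float, float, float, float]],
    cat: dict[str, tuple[list, list]],
    com: dict[str, tuple[float, float]],
) -> SiteProfile:
    continuous = {
        v: {SURVIVOR: (ms, ss), DEATH: (md, sd)} for v, (ms, ss, md, sd) in cont.items()
    }
    categorical = {}
    for var, (surv_pct, death_pct) in cat.items():
        levels = CATEGORICAL_LEVELS[var]
        categorical[var] = {
            SURVIVOR: _pct(dict(zip(levels, surv_pct))),
            DEATH: _pct(dict(zip(levels, death_pct))),
        }
    comorbidity = {v: {SURVIVOR: s / 100.0, DEATH: d / 100.0} for v, (s, d) in com.items()}
    return SiteProfile(
        site_id=site_id,
        prevalence=deaths / total,
        continuous=continuous,
        categorical=categorical,
        comorbidity=comorbidity,
    )


def default_profiles() -> list[SiteProfile]:
    """The three built-in hospital profiles (A, B, C).

    Parameters are the published class-conditional baseline demographics of
    three Korean tertiary-hospital ED cohorts (2016–2017): per-class mean ± SD
    for age and the six vitals, per-class category percentages for the
    categorical triage variables, and per-class comorbidity prevalences.
    Outcome prevalences come from the printed event counts
    (A: 445/87,670; B: 464/83,363; C: 379/54,423).
    """
    a = _site(
        "A",
        deaths=445,
        total=87_670,
        cont={
            "age": (55.3, 17.5, 67.2, 14.3),
            "pulse": (89.5, 20.1, 108.0, 25.4),
            "sbp": (129.9, 25.0, 118.0, 32.3),
            "dbp": (77.1, 15.4, 68.1, 20.1),
            "resp_rate": (19.0, 2.4, 22.7, 5.4),
            "spo2": (97.3, 3.2, 91.8, 9.8),
            "temperature": (37.0, 0.8, 36.8, 1.0),
        },
        cat={
            "sex": ([48.8, 51.2], [59.6, 40.4]),
            "day_of_week": ([41.5, 28.3, 13.9, 16.3], [42.0, 30.8, 10.6, 16.6]),
            "shift": ([46.1, 36.2, 17.7], [49.0, 28.8, 22.2]),
            "ktas": ([0.6, 9.1, 46.6, 36.0, 7.7], [16.4, 33.3, 39.8, 10.1, 0.4]),
            "consciousness": ([97.4, 1.5, 0.9, 0.2], [70.8, 11.2, 12.8, 5.2]),
            "route": ([79.8, 20.2], [63.4, 36.6]),
            "transport": ([20.3, 79.7], [71.2, 28.8]),
        },
        com={
            "myocardial_infarction": (1.5, 3.6),
            "congestive_heart_failure": (5.0, 8.5),
            "peripheral_vascular_disease": (2.4, 3.1),
            "stroke": (8.8, 10.8),
            "dementia": (3.3, 5.8),
            "chronic_pulmonary_disease": (7.0, 12.4),
            "rheumatoid_disease": (1.3, 1.1),
            "diabetes": (3.9, 4.0),
            "diabetes_with_complication": (11.2, 16.9),
            "hemiplegia": (0.6, 0.4),
            "kidney_disease": (5.7, 5.6),
            "local_tumor_leukemia_lymphoma": (35.8, 73.9),
            "metastatic_solid_tumor": (6.3, 19.6),
            "mild_liver_disease": (8.8, 12.4),
            "severe_liver_disease": (1.5, 2.5),
        },
    )
    b = _site(
        "B",
        deaths=464,
        total=83_363,
        cont={
            "age": (51.4, 19.1, 72.8, 14.4),
            "pulse": (87.9, 17.6, 102.2, 28.1),
            "sbp": (131.7, 24.4, 105.7, 30.5),
            "dbp": (78.8, 15.4, 63.0, 20.0),
            "resp_rate": (16.2, 3.1, 22.0, 6.3),
            "spo2": (98.4, 2.2, 93.3, 8.0),
            "temperature": (36.8, 0.7, 36.6, 1.2),
        },
        cat={
            "sex": ([47.2, 52.8], [52.8, 47.2]),
            "day_of_week": ([40.2, 30.6, 13.7, 15.5], [40.1, 30.8, 12.7, 16.4]),
            "shift": ([42.4, 36.5, 21.1], [43.1, 39.4, 17.5]),
            "ktas": ([0.6, 10.6, 67.7, 15.8, 5.3], [18.1, 53.2, 27.4, 0.9, 0.4]),
            "consciousness": ([95.6, 2.4, 1.8, 0.2], [44.0, 19.0, 26.7, 10.3]),
            "route": ([78.4, 21.6], [46.6, 53.4]),
            "transport": ([21.1, 78.9], [75.4, 24.6]),
        },
        com={
            "myocardial_infarction": (1.5, 4.7),
            "congestive_heart_failure": (2.5, 10.1),
            "peripheral_vascular_disease": (0.8, 2.4),
            "stroke": (5.8, 10.3),
            "dementia": (1.1, 3.2),
            "chronic_pulmonary_disease": (4.6, 8.4),
            "rheumatoid_disease": (1.0, 1.1),
            "diabetes": (2.8, 5.8),
            "diabetes_with_complication": (10.5, 28.2),
            "hemiplegia": (0.4, 1.5),
            "kidney_disease": (3.5, 8.8),
            "local_tumor_leukemia_lymphoma": (5.2, 9.5),
            "metastatic_solid_tumor": (1.0, 2.4),
            "mild_liver_disease": (3.0, 6.9),
            "severe_liver_disease": (1.0, 5.4),
        },
    )
    c = _site(
        "C",
        deaths=379,
        total=54_423,
        cont={
            "age": (51.7, 20.4, 72.5, 13.6),
            "pulse": (89.3, 19.0, 100.8, 22.0),
            "sbp": (134.1, 24.4, 112.6, 31.8),
            "dbp": (81.9, 15.3, 73.3, 21.2),
            "resp_rate": (20.9, 2.9, 22.0, 7.2),
            "spo2": (97.5, 3.0, 88.9, 12.2),
            "temperature": (36.8, 0.8, 36.1, 1.1),
        },
        cat={
            "sex": ([44.9, 55.1], [57.5, 42.5]),
            "day_of_week": ([39.8, 31.6, 13.6, 15.1], [41.2, 27.7, 12.7, 18.5]),
            "shift": ([38.1, 38.8, 23.1], [43.0, 33.8, 23.2]),
            "ktas": ([1.2, 13.6, 63.0, 16.6, 5.5], [52.0, 35.4, 12.1, 0.5, 0.0]),
            "consciousness": ([94.3, 4.2, 1.3, 0.2], [28.2, 17.9, 17.4, 36.4]),
            "route": ([85.2, 14.8], [76.3, 23.7]),
            "transport": ([30.3, 69.7], [87.3, 12.7]),
        },
        com={
            "myocardial_infarction": (2.0, 6.1),
            "congestive_heart_failure": (2.5, 5.5),
            "peripheral_vascular_disease": (0.9, 1.3),
            "stroke": (5.0, 6.3),
            "dementia": (2.3, 6.6),
            "chronic_pulmonary_disease": (3.3, 5.3),
            "rheumatoid_disease": (0.7, 0.8),
            "diabetes": (2.7, 3.7),
            "diabetes_with_complication": (10.7, 28.0),
            "hemiplegia": (0.9, 1.1),
            "kidney_disease": (2.8, 4.5),
            "local_tumor_leukemia_lymphoma": (2.9, 5.0),
            "metastatic_solid_tumor": (0.6, 4.0),
            "mild_liver_disease": (2.7, 4.0),
            "severe_liver_disease": (0.5, 1.3),
        },
    )
    return [a, b, c]
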