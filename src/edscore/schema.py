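"""Record schema shared by every stage of the pipeline.

A triage record is one ED visit captured at arrival: demographics, arrival
metadata, the Korea Triage and Acuity Scale (KTAS) level, AVPU consciousness,
six vital signs, comorbidity history flags, two exclusion flags and the binary
2-day-mortality outcome. Cohorts are plain pandas DataFrames with one column
per field; booleans are stored as 0/1 so CSV round-trips are lossless.
"""

from __future__ import annotations

# Continuous triage variables with physiological truncation bounds used by the
# generator (draws outside are impossible by construction).
CONTINUOUS_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 105.0),
    "pulse": (20.0, 250.0),
    "sbp": (40.0, 260.0),
    "dbp": (20.0, 160.0),
    "resp_rate": (4.0, 60.0),
    "spo2": (40.0, 100.0),
    "temperature": (33.0, 42.0),
}

CONTINUOUS_VARS: list[str] = list(CONTINUOUS_BOUNDS)

# Categorical triage variables and their category labels. KTAS is ordinal
# 1 (most severe) .. 5 (least severe) but is drawn and modelled as categorical.
CATEGORICAL_LEVELS: dict[str, list] = {
    "sex": ["male", "female"],
    "day_of_week": ["midweek", "weekend", "friday", "monday"],
    "shift": ["day", "evening", "night"],
    "ktas": [1, 2, 3, 4, 5],
    "consciousness": ["alert", "verbal", "painful", "unconscious"],
    "route": ["direct", "other"],
    "transport": ["ambulance", "other"],
}

CATEGORICAL_VARS: list[str] = list(CATEGORICAL_LEVELS)

# Charlson-style comorbidity flags recorded from the 5 preceding years of
# diagnoses (binary 0/1 columns).
COMORBIDITY_VARS: list[str] = [
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "stroke",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatoid_disease",
    "diabetes",
    "diabetes_with_complication",
    "hemiplegia",
    "kidney_disease",
    "local_tumor_leukemia_lymphoma",
    "metastatic_solid_tumor",
    "mild_liver_disease",
    "severe_liver_disease",
]

# The 14 variables available at the moment of triage; default candidate set
# for variable ranking (comorbidity history can be added explicitly).
TRIAGE_VARS: list[str] = CONTINUOUS_VARS + CATEGORICAL_VARS

OUTCOME = "death_2day"
EXCLUSION_FLAGS = ["doa", "trauma"]

RECORD_COLUMNS: list[str] = (
    TRIAGE_VARS + COMORBIDITY_VARS + EXCLUSION_FLAGS + [OUTCOME]
)

BOOLEAN_COLUMNS: list[str] = COMORBIDITY_VARS + EXCLUSION_FLAGS + [OUTCOME]

SURVIVOR, DEATH = "survivor", "death"
CLASSES = (SURVIVOR, DEATH)
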