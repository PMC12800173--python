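"""Column dictionary and neuropsychological test battery definitions.

Everything downstream — the synthetic generator, eligibility filters,
normative scoring, the Level II classifier and the clustering features —
speaks the tidy column vocabulary defined here: one row per
participant-visit, snake_case names.
"""

from __future__ import annotations

# --- Neuropsychological battery: 10 tests, 2 per cognitive domain ---------

#: Tests where a *larger* raw score means *worse* performance (timed tests).
HIGHER_IS_WORSE: dict[str, bool] = {
    "tmt_a": True,
    "block_span": False,
    "fab": False,
    "tmt_b_minus_a": True,
    "wordlist_total": False,
    "wordlist_delayed": False,
    "judgement_line_orientation": False,
    "moca_clock": False,
    "phonemic_fluency": False,
    "moca_naming": False,
}

TESTS: list[str] = list(HIGHER_IS_WORSE)

#: Five cognitive domains, two independent tests each (Level II battery).
DOMAINS: dict[str, tuple[str, str]] = {
    "attention": ("tmt_a", "block_span"),
    "executive": ("fab", "tmt_b_minus_a"),
    "memory": ("wordlist_total", "wordlist_delayed"),
    "visuospatial": ("judgement_line_orientation", "moca_clock"),
    "language": ("phonemic_fluency", "moca_naming"),
}

# --- Demographics / covariates --------------------------------------------

#: Sex coding used everywhere (generation, regression, z-scoring).
SEX_FEMALE, SEX_MALE = 0, 1

COVARIATES = ["age", "education_years", "sex"]

KEY_COLUMNS = ["participant_id", "visit", "group"]

# --- Clinical scales and flags --------------------------------------------

PDQ_ADL_ITEMS = [f"pdq39_item_{i}" for i in range(11, 17)]  # items 11-16
PDQ_SCC_ITEMS = [f"pdq39_item_{i}" for i in range(30, 34)]  # items 30-33

COMORBIDITY_FLAGS = ["cardiovascular", "hypertension", "diabetes", "smoking", "alcohol"]
PSYCHIATRIC_FLAGS = ["bipolar", "schizophrenia"]
NEURO_FLAGS = ["seizures", "stroke", "tbi", "brain_tumour"]
HC_RISK_FLAGS = ["family_history"] + COMORBIDITY_FLAGS

CLINICAL_COLUMNS = [
    "moca_total",
    "updrs_1_1",
    "updrs_iii",
    "hoehn_yahr",
    "bdi",
    "sas",
    "rbdsq",
    "disease_duration",
    "age_at_onset",
]

BASELINE_COLUMNS = (
    KEY_COLUMNS
    + COVARIATES
    + TESTS
    + CLINICAL_COLUMNS
    + PDQ_ADL_ITEMS
    + PDQ_SCC_ITEMS
    + COMORBIDITY_FLAGS
    + PSYCHIATRIC_FLAGS
    + NEURO_FLAGS
    + ["family_history", "death_year"]
)


def z_col(test: str) -> str:
    """Column name for the z-score of a test."""
    return f"z_{test}"


def adl_subscore(df):
    """PDQ-39 activities-of-daily-living subscore: plain sum of items 11-16."""
    return df[PDQ_ADL_ITEMS].sum(axis=1)


def scc_subscore(df):
    """PDQ-39 subjective cognitive complaints: plain sum of items 30-33."""
    return df[PDQ_SCC_ITEMS].sum(axis=1)
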