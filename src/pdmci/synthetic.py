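"""Synthetic cohort generator.

Emulates the statistical structure of a monocentric Parkinson's cohort with
an in-depth neuropsychological baseline assessment and annual follow-up:

* healthy-control test scores linear in age / education / sex plus Gaussian
  noise (the normative-regression data-generating model);
* people with PD drawn from three latent cognitive classes — NC (cognitively
  normal), early-MCI (sub-threshold deficits concentrated on a couple of
  executive / attention / memory tests) and MCI (deficits >= 1.5 SD across
  several domains, including visuospatial);
* class-conditional global cognition (MoCA), clinician- and patient-reported
  measures, motor staging and comorbidity flags;
* annual follow-up visits with class-specific MoCA decline slopes and an
  exponential proportional-hazards time to clinically relevant cognitive
  worsening (MDS-UPDRS 1.1 reaching >= 3).

Ground-truth latent classes are returned alongside the tables so every
downstream stage can be validated without access to any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    COMORBIDITY_FLAGS,
    HIGHER_IS_WORSE,
    KEY_COLUMNS,
    NEURO_FLAGS,
    PDQ_ADL_ITEMS,
    PDQ_SCC_ITEMS,
    PSYCHIATRIC_FLAGS,
    TESTS,
)

LATENT_CLASSES = ("NC", "earlyMCI", "MCI")

# Per-test normative regression truth: intercept, f_age, f_ed, f_sex, residual SD.
# Units are the instrument's native units (seconds for the timed trail-making
# scores, points otherwise); sex is coded 0 = female, 1 = male.
DEFAULT_NORMATIVE_COEFS: dict[str, tuple[float, float, float, float, float]] = {
    "tmt_a": (10.0, 0.45, -0.50, 2.0, 10.0),
    "block_span": (10.5, -0.040, 0.080, 0.2, 1.8),
    "fab": (18.5, -0.035, 0.100, -0.2, 1.5),
    "tmt_b_minus_a": (15.0, 0.55, -0.80, 2.0, 16.0),
    "wordlist_total": (30.0, -0.120, 0.250, -1.5, 3.5),
    "wordlist_delayed": (10.5, -0.045, 0.080, -0.5, 1.6),
    "judgement_line_orientation": (26.0, -0.050, 0.200, 1.0, 3.5),
    "moca_clock": (3.1, -0.006, 0.015, 0.0, 0.45),
    "phonemic_fluency": (10.0, -0.030, 0.300, -0.5, 3.0),
    "moca_naming": (3.0, -0.003, 0.008, 0.0, 0.30),
}

# Latent-class deficit shifts in control-SD units (positive = worse).
# early-MCI: 1.0-1.1 SD shifts on two executive/memory tests — clinically
# meaningful but mostly below the two-test Level II impairment criterion.
# MCI: >= 1.5 SD across multiple domains including visuospatial.
DEFAULT_CLASS_DEFICITS: dict[str, dict[str, float]] = {
    "NC": {},
    "earlyMCI": {
        "tmt_b_minus_a": 1.1,
        "wordlist_delayed": 1.0,
    },
    "MCI": {
        "tmt_a": 1.6,
        "block_span": 1.0,
        "fab": 1.5,
        "tmt_b_minus_a": 1.8,
        "wordlist_total": 1.6,
        "wordlist_delayed": 1.8,
        "judgement_line_orientation": 1.5,
        "moca_clock": 1.0,
        "phonemic_fluency": 0.8,
        "moca_naming": 0.5,
    },
}

#: A planted deficit of at least this many control SDs marks a test as
#: "planted impaired" in the ground truth.
PLANTED_IMPAIRMENT_SD = 1.0


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults emulate the eligible study population of the motivating cohort:
    226 healthy controls, 115 people with PD (older, more often male), latent
    class proportions matching the reported four-way subgroup sizes, and up
    to 8 annual follow-up visits for PD participants.
    """

    n_controls: int = 226
    n_pd: int = 115
    # 49+1 reference-NC, 26 early, 39 MCI out of 115
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.435, "earlyMCI": 0.226, "MCI": 0.339}
    )
    age_range_pd: tuple[float, float] = (38.0, 88.0)
    age_range_hc: tuple[float, float] = (21.0, 86.0)
    male_fraction_pd: float = 0.72
    male_fraction_hc: float = 0.54
    education_range: tuple[int, int] = (6, 22)
    normative_coefs: dict[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMATIVE_COEFS)
    )
    class_deficits: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_DEFICITS.items()}
    )
    moca_class_means: dict[str, float] = field(
        default_factory=lambda: {"NC": 27.0, "earlyMCI": 25.5, "MCI": 23.5}
    )
    moca_sd: float = 1.6
    moca_hc_mean: float = 27.5
    # PD comorbidity / lifestyle prevalences per latent class; generated
    # controls emulate an already-screened reference group (risk-flag free),
    # so the eligibility filters are near-identity on default synthetic data.
    # Prevalences rise with cognitive class: comorbidity burden is part of
    # what separates the data-driven clusters.
    comorbidity_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "cardiovascular": {"NC": 0.15, "earlyMCI": 0.32, "MCI": 0.35},
            "hypertension": {"NC": 0.25, "earlyMCI": 0.42, "MCI": 0.45},
            "diabetes": {"NC": 0.06, "earlyMCI": 0.15, "MCI": 0.16},
            "smoking": {"NC": 0.25, "earlyMCI": 0.36, "MCI": 0.38},
            "alcohol": {"NC": 0.20, "earlyMCI": 0.30, "MCI": 0.32},
        }
    )
    followup_years: int = 8
    #: log hazard ratio (vs NC) for the MDS-UPDRS 1.1 >= 3 endpoint
    decline_hazard_log_hr: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "earlyMCI": 0.9, "MCI": 1.6}
    )
    baseline_hazard: float = 0.06  # NC events per year
    moca_decline_slopes: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.25, "earlyMCI": 0.55, "MCI": 0.90}
    )
    moca_visit_noise_sd: float = 1.0
    death_rate: float = 0.012  # per year, independent of cognition
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls <= 0 or self.n_pd <= 0:
            raise ValueError("cohort sizes must be positive")
        props = np.array([self.class_proportions[c] for c in LATENT_CLASSES])
        if abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValueError("class_proportions must be a simplex over NC/earlyMCI/MCI")
        for test, coefs in self.normative_coefs.items():
            if coefs[4] <= 0:
                raise ValueError(f"residual SD must be positive for {test}")
        for test, shift in self.class_deficits.get("NC", {}).items():
            if shift != 0:
                raise ValueError("NC class must have zero deficit shifts")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.followup_years < 0:
            raise ValueError("followup_years must be non-negative")


def _truncated_normal(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, low, high)


def _control_scores(rng, spec: CohortSpec, age, ed, sex) -> dict[str, np.ndarray]:
    """Raw test scores under the normative linear model (no clipping, so
    regression refits recover the planted coefficients exactly in expectation)."""
    n = len(age)
    out = {}
    for test in TESTS:
        b0, b_age, b_ed, b_sex, sd = spec.normative_coefs[test]
        out[test] = b0 + b_age * age + b_ed * ed + b_sex * sex + rng.normal(0, sd, n)
    return out


def generate_baseline(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the baseline participant-visit table and its ground truth.

    Returns
    -------
    baseline : DataFrame
        One row per participant at visit 0, full column dictionary.
    truth : DataFrame
        participant_id, latent_class (PD only; controls carry ``HC``),
        planted_impaired_tests (comma-joined names, empty for latent NC).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_hc, n_pd = spec.n_controls, spec.n_pd
    n = n_hc + n_pd
    group = np.array(["HC"] * n_hc + ["PD"] * n_pd)
    pid = np.array([f"{g}{i:04d}" for i, g in enumerate(group)])

    # latent classes for PD
    props = [spec.class_proportions[c] for c in LATENT_CLASSES]
    latent_pd = rng.choice(LATENT_CLASSES, size=n_pd, p=props)
    latent = np.array(["HC"] * n_hc + list(latent_pd), dtype=object)

    # demographics: MCI classes are older with longer disease duration
    age = np.empty(n)
    age[:n_hc] = _truncated_normal(rng, 60.0, 12.0, *spec.age_range_hc, size=n_hc)
    class_age_shift = {"NC": 0.0, "earlyMCI": 5.5, "MCI": 7.0}
    pd_age_mean = 63.0 + np.array([class_age_shift[c] for c in latent_pd])
    age[n_hc:] = np.clip(rng.normal(pd_age_mean, 8.0), *spec.age_range_pd)

    sex = np.concatenate(
        [
            (rng.random(n_hc) < spec.male_fraction_hc).astype(int),
            (rng.random(n_pd) < spec.male_fraction_pd).astype(int),
        ]
    )
    ed = rng.integers(spec.education_range[0], spec.education_range[1] + 1, size=n).astype(float)

    # neuropsychological scores: normative model + class deficit shifts
    scores = _control_scores(rng, spec, age, ed, sex)
    for test in TESTS:
        sd = spec.normative_coefs[test][4]
        shift = np.array(
            [0.0 if c == "HC" else spec.class_deficits.get(c, {}).get(test, 0.0) for c in latent]
        )
        sign = 1.0 if HIGHER_IS_WORSE[test] else -1.0
        scores[test] = scores[test] + sign * shift * sd

    df = pd.DataFrame({"participant_id": pid, "visit": 0, "group": group})
    df["age"] = np.round(age, 1)
    df["sex"] = sex
    df["education_years"] = ed
    for test in TESTS:
        df[test] = np.round(scores[test], 1)

    # global cognition and clinical scales, class-conditional
    moca_mean = np.array(
        [spec.moca_hc_mean if c == "HC" else spec.moca_class_means[c] for c in latent]
    )
    df["moca_total"] = np.clip(np.round(rng.normal(moca_mean, spec.moca_sd)), 0, 30).astype(int)

    updrs11_probs = {
        "HC": [0.74, 0.21, 0.04, 0.01, 0.0],
        "NC": [0.70, 0.25, 0.05, 0.00, 0.0],
        "earlyMCI": [0.50, 0.38, 0.10, 0.02, 0.0],
        "MCI": [0.35, 0.40, 0.18, 0.06, 0.01],
    }
    df["updrs_1_1"] = [rng.choice(5, p=updrs11_probs[c]) for c in latent]

    updrs3_mean = {"HC": 2.0, "NC": 25.0, "earlyMCI": 32.0, "MCI": 33.0}
    df["updrs_iii"] = np.clip(
        np.round(rng.normal([updrs3_mean[c] for c in latent], 9.0)), 0, 132
    ).astype(int)

    hy_probs = {
        "HC": [1.0, 0.0, 0.0, 0.0],
        "NC": [0.45, 0.45, 0.09, 0.01],
        "earlyMCI": [0.12, 0.52, 0.29, 0.07],
        "MCI": [0.10, 0.50, 0.32, 0.08],
    }
    df["hoehn_yahr"] = [rng.choice([1, 2, 3, 4], p=hy_probs[c]) for c in latent]
    df.loc[df["group"] == "HC", "hoehn_yahr"] = np.nan

    bdi_mean = {"HC": 4.0, "NC": 7.0, "earlyMCI": 8.5, "MCI": 10.0}
    df["bdi"] = np.clip(
        np.round(rng.normal([bdi_mean[c] for c in latent], 3.5)), 0, 63
    ).astype(int)
    sas_mean = {"HC": 9.0, "NC": 11.0, "earlyMCI": 12.5, "MCI": 14.0}
    df["sas"] = np.clip(
        np.round(rng.normal([sas_mean[c] for c in latent], 4.0)), 0, 42
    ).astype(int)
    rbdsq_lam = {"HC": 1.3, "NC": 3.0, "earlyMCI": 4.0, "MCI": 4.2}
    df["rbdsq"] = np.clip(rng.poisson([rbdsq_lam[c] for c in latent]), 0, 13)

    # disease-related factors (PD only)
    dur = np.full(n, np.nan)
    dur_mean = {"NC": 3.0, "earlyMCI": 5.5, "MCI": 6.0}
    dur[n_hc:] = np.round(
        rng.gamma(2.0, np.array([dur_mean[c] for c in latent_pd]) / 2.0), 1
    )
    df["disease_duration"] = dur
    df["age_at_onset"] = np.round(df["age"] - df["disease_duration"], 1)

    # patient-reported PDQ-39 items (each 0-4)
    adl_p = {"HC": 0.02, "NC": 0.12, "earlyMCI": 0.20, "MCI": 0.30}
    scc_p = {"HC": 0.05, "NC": 0.10, "earlyMCI": 0.20, "MCI": 0.30}
    for col in PDQ_ADL_ITEMS:
        df[col] = rng.binomial(4, [adl_p[c] for c in latent])
    for col in PDQ_SCC_ITEMS:
        df[col] = rng.binomial(4, [scc_p[c] for c in latent])

    # comorbidity / lifestyle flags: PD only by default (controls emulate an
    # already risk-screened reference group)
    for flag in COMORBIDITY_FLAGS:
        prev = spec.comorbidity_prevalences.get(flag, {})
        p = np.array([0.0 if c == "HC" else prev.get(c, 0.0) for c in latent])
        df[flag] = rng.binomial(1, p)
    for flag in PSYCHIATRIC_FLAGS + NEURO_FLAGS + ["family_history"]:
        df[flag] = 0

    # death times (years since baseline), independent of cognition
    death = rng.exponential(1.0 / spec.death_rate, size=n)
    df["death_year"] = np.where(death <= spec.followup_years, np.round(death, 2), np.nan)

    planted = []
    for c in latent:
        if c in ("HC", "NC"):
            planted.append("")
        else:
            tests = [
                t
                for t in TESTS
                if spec.class_deficits.get(c, {}).get(t, 0.0) >= PLANTED_IMPAIRMENT_SD
            ]
            planted.append(",".join(tests))
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "latent_class": latent,
            "planted_impaired_tests": planted,
        }
    )
    return df, truth


def generate_followups(
    baseline: pd.DataFrame, truth: pd.DataFrame, spec: CohortSpec
) -> pd.DataFrame:
    """Annual follow-up visits for PD participants.

    MoCA declines with a class-specific slope plus visit noise; the
    MDS-UPDRS 1.1 >= 3 endpoint time is drawn from an exponential
    proportional-hazards model with the spec's class log hazard ratios.
    Visits after death are dropped. Returns baseline + follow-up rows in one
    longitudinal table with a ``years_since_baseline`` column.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    truth_map = truth.set_index("participant_id")["latent_class"]
    unknown = set(baseline["participant_id"]) - set(truth_map.index)
    if unknown:
        raise ValueError(f"participants missing from ground truth: {sorted(unknown)[:3]}")

    base = baseline.copy()
    base["years_since_baseline"] = 0.0
    rows = [base]
    pd_rows = baseline[baseline["group"] == "PD"]
    for _, row in pd_rows.iterrows():
        cls = truth_map[row["participant_id"]]
        slope = spec.moca_decline_slopes[cls]
        hazard = spec.baseline_hazard * np.exp(spec.decline_hazard_log_hr[cls])
        event_time = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        death_year = row["death_year"]
        last = spec.followup_years
        if death_year == death_year:  # not NaN
            last = min(last, int(np.floor(death_year)))
        for year in range(1, int(last) + 1):
            visit = row.copy()
            visit["visit"] = year
            visit["years_since_baseline"] = float(year)
            visit["age"] = round(row["age"] + year, 1)
            moca = row["moca_total"] - slope * year + rng.normal(0, spec.moca_visit_noise_sd)
            visit["moca_total"] = int(np.clip(round(moca), 0, 30))
            if year >= event_time:
                visit["updrs_1_1"] = max(3, int(row["updrs_1_1"]))
            else:
                step = rng.choice([0, 0, 0, 1])
                visit["updrs_1_1"] = int(min(row["updrs_1_1"] + step, 2))
            rows.append(visit.to_frame().T)
    longi = pd.concat(rows, ignore_index=True)
    longi = longi.sort_values(["participant_id", "visit"], kind="stable").reset_index(drop=True)
    # concat of mixed frames upcasts; restore numeric dtypes
    for col in longi.columns:
        if col not in ("participant_id", "group"):
            longi[col] = pd.to_numeric(longi[col])
    return longi


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank non-key cells completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must be in [0, 1)")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    cols = [c for c in out.columns if c not in KEY_COLUMNS]
    mask = rng.random((len(out), len(cols))) < rate
    values = out[cols].to_numpy(dtype=object)
    values[mask] = np.nan
    out[cols] = values
    for c in cols:
        try:
            out[c] = pd.to_numeric(out[c])
        except (ValueError, TypeError):
            pass
    return out
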