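import numpy as np
import pandas as pd
import pytest

from pdmci.normative import fit_normative_models, score_cohort
from pdmci.synthetic import CohortSpec, generate_baseline, generate_followups


@pytest.fixture(scope="session")
def small_spec():
    """Reduced cohort for fast end-to-end fixtures."""
    return CohortSpec(n_controls=120, n_pd=80, followup_years=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    baseline, truth = generate_baseline(small_spec)
    return baseline, truth


@pytest.fixture(scope="session")
def small_longitudinal(small_spec, small_cohort):
    baseline, truth = small_cohort
    return generate_followups(baseline, truth, small_spec)


@pytest.fixture(scope="session")
def scored_pd(small_cohort):
    """PD baseline with z-score columns appended (models fitted on HC)."""
    baseline, truth = small_cohort
    controls = baseline[baseline["group"] == "HC"]
    models = fit_normative_models(controls)
    pd_base = baseline[baseline["group"] == "PD"].reset_index(drop=True)
    z = score_cohort(pd_base, models)
    scored = pd.concat([pd_base, z.drop(columns="participant_id")], axis=1)
    return scored, truth


def two_blobs(n_per=30, sep=20.0, dim=4, seed=0):
    """Two well-separated Gaussian blobs with identity covariance."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per, dim))
    b = rng.normal(0.0, 1.0, (n_per, dim)) + sep
    X = np.vstack([a, b])
    y = np.array([0] * n_per + [1] * n_per)
    return X, y
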