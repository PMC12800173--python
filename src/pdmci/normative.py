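"""Regression-based normative scoring of neuropsychological tests.

Because population-specific normative tables are rarely available, the
expected ("normative") score for each test is modelled on the healthy
control reference sample by ordinary least squares on the three standard
non-pathological confounders of cognitive performance:

    Y_exp = Y + f_age * Age + f_ed * Education + f_sex * Sex

and individual performance is expressed as a z-score relative to this
covariate-adjusted expectation:

    z = (Y_obs - Y_exp) / SD

where SD is the residual standard deviation of the control regression
(unbiased, n - 4 denominator). For timed tests, where a larger raw score is
worse, the z-score is sign-flipped so that lower z always means worse
performance across the whole battery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .schema import COVARIATES, HIGHER_IS_WORSE, TESTS, z_col

N_PARAMS = 4  # intercept + age + education + sex


class NormativeFitError(ValueError):
    """Raised when a per-test normative regression cannot be fitted."""


@dataclass
class NormativeModel:
    """Fitted per-test normative regression."""

    test_name: str
    intercept: float
    f_age: float
    f_ed: float
    f_sex: float
    sd: float
    higher_is_worse: bool
    n_reference: int
    degenerate: bool = False  # zero residual spread (constant response)

    def expected(self, age, education_years, sex):
        """Covariate-adjusted normative expectation Y_exp."""
        return (
            self.intercept
            + self.f_age * np.asarray(age, dtype=float)
            + self.f_ed * np.asarray(education_years, dtype=float)
            + self.f_sex * np.asarray(sex, dtype=float)
        )

    def to_dict(self) -> dict:
        return asdict(self)


def fit_normative_models(
    controls: pd.DataFrame,
    tests: list[str] | None = None,
    directions: dict[str, bool] | None = None,
) -> dict[str, NormativeModel]:
    """Fit one OLS normative regression per test on the control sample.

    Rows with a missing score or covariate are dropped per test
    (complete-case fitting). Raises :class:`NormativeFitError` naming the
    test when fewer than 5 usable rows remain or the design is collinear.
    """
    tests = tests or TESTS
    directions = directions or HIGHER_IS_WORSE
    if "group" in controls.columns and (controls["group"] == "PD").any():
        raise ValueError("normative reference sample must not contain PD rows")

    models: dict[str, NormativeModel] = {}
    for test in tests:
        cols = [test] + COVARIATES
        missing = [c for c in cols if c not in controls.columns]
        if missing:
            raise KeyError(f"column missing for normative fit: {missing[0]!r}")
        sub = controls[cols].dropna()
        n = len(sub)
        if n <= N_PARAMS:
            raise NormativeFitError(
                f"{test}: need more than {N_PARAMS} complete reference rows, got {n}"
            )
        X = np.column_stack(
            [np.ones(n), sub["age"], sub["education_years"], sub["sex"]]
        ).astype(float)
        y = sub[test].to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < N_PARAMS:
            raise NormativeFitError(f"{test}: collinear covariates in reference sample")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.sqrt(resid @ resid / (n - N_PARAMS)))
        if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            sd = 0.0  # constant response up to round-off
        models[test] = NormativeModel(
            test_name=test,
            intercept=float(beta[0]),
            f_age=float(beta[1]),
            f_ed=float(beta[2]),
            f_sex=float(beta[3]),
            sd=sd,
            higher_is_worse=bool(directions[test]),
            n_reference=n,
            degenerate=(sd == 0.0),
        )
    return models


def z_score(model: NormativeModel, y_obs, age, education_years, sex):
    """Z-score one or more observations under a fitted normative model.

    Missing observed scores propagate to missing z (never silently zero).
    The returned z is oriented so that lower always means worse: for
    higher-is-worse tests the raw standardised residual is negated.
    """
    if model.sd <= 0:
        raise ZeroDivisionError(
            f"{model.test_name}: degenerate normative model (sd = 0), z undefined"
        )
    y_obs = np.asarray(y_obs, dtype=float)
    z_raw = (y_obs - model.expected(age, education_years, sex)) / model.sd
    return -z_raw if model.higher_is_worse else z_raw


def score_cohort(table: pd.DataFrame, models: dict[str, NormativeModel]) -> pd.DataFrame:
    """Apply fitted normative models to a participant-visit table.

    Returns a frame indexed like ``table`` with one ``z_<test>`` column per
    model plus a ``profile_complete`` flag (all battery z present).
    """
    for c in COVARIATES:
        if c not in table.columns:
            raise KeyError(f"covariate column missing: {c!r}")
    out = pd.DataFrame(index=table.index)
    if "participant_id" in table.columns:
        out["participant_id"] = table["participant_id"]
    for test, model in models.items():
        if test not in table.columns:
            raise KeyError(f"test column missing: {test!r}")
        out[z_col(test)] = z_score(
            model,
            table[test],
            table["age"],
            table["education_years"],
            table["sex"],
        )
    zcols = [z_col(t) for t in models]
    out["profile_complete"] = out[zcols].notna().all(axis=1)
    return out


def models_to_frame(models: dict[str, NormativeModel]) -> pd.DataFrame:
    """Serialisable table of fitted normative coefficients."""
    return pd.DataFrame([m.to_dict() for m in models.values()])
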