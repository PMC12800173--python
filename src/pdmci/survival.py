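"""Longitudinal validation of the diagnostic subgroups.

Events reflect progression to cognitive impairment that affects daily
living, beyond mild deficits: MoCA total <= 21 (the MMSE < 26 equivalent)
or physician-rated MDS-UPDRS 1.1 >= 3 (moderate impairment). Participants
already at the endpoint at baseline are excluded, deaths before the event
right-censor, otherwise follow-up ends at the last visit. Cox proportional
hazards models (Efron tie handling) compare subgroups against the
concordant-NC reference, adjusted for age, years of education and the
baseline score of the outcome feature; group differences are additionally
tested with the global log-rank test plus BH-adjusted pairwise post-hocs,
and the proportional-hazards assumption is checked per covariate via
scaled Schoenfeld residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from lifelines.statistics import proportional_hazard_test

from .stats import bh_adjust

OUTCOMES = {
    "moca": {"column": "moca_total", "threshold": 21, "direction": "le"},
    "updrs_1_1": {"column": "updrs_1_1", "threshold": 3, "direction": "ge"},
}

DEFAULT_COVARIATES = ["age", "education_years", "baseline_score"]


@dataclass
class CoxFitResult:
    outcome: str
    n: int
    n_events: int
    coefficients: pd.DataFrame  # log-HR, HR, CI, p per covariate
    global_logrank_p: float | None
    pairwise_logrank: pd.DataFrame | None
    ph_verdicts: dict = field(default_factory=dict)
    estimable: bool = True
    note: str = ""


def derive_events(
    longitudinal: pd.DataFrame,
    outcome: str,
    subgroups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build one survival record per participant for an outcome.

    Time is measured since PD diagnosis (baseline disease duration plus
    years since baseline). The event is the first visit at which the
    outcome crosses its threshold; baseline-event participants are dropped;
    death before the event censors at the death time, otherwise censoring
    is at the last visit.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {list(OUTCOMES)}")
    cfg = OUTCOMES[outcome]
    col, thr = cfg["column"], cfg["threshold"]

    crossed = (
        (longitudinal[col] <= thr) if cfg["direction"] == "le" else (longitudinal[col] >= thr)
    )
    df = longitudinal.assign(_crossed=crossed)

    records = []
    for pid, visits in df[df["group"] == "PD"].groupby("participant_id", sort=True):
        if "visit" in visits.columns:
            visits = visits.sort_values("visit")
        times = visits["years_since_baseline"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{pid}: non-monotone visit times")
        base = visits.iloc[0]
        if base["years_since_baseline"] != 0:
            continue  # no baseline visit for this outcome
        if base["_crossed"]:
            continue  # endpoint already reached at baseline: onset time unknown
        origin = float(base["disease_duration"])
        hit = visits[visits["_crossed"]]
        death_year = base.get("death_year", np.nan)
        if len(hit) > 0:
            t = origin + float(hit.iloc[0]["years_since_baseline"])
            event, reason = True, "none"
        elif death_year == death_year:
            t = origin + float(death_year)
            event, reason = False, "death"
        else:
            t = origin + float(visits.iloc[-1]["years_since_baseline"])
            event, reason = False, "end_of_followup"
        if t <= 0:
            continue  # no usable follow-up time
        records.append(
            {
                "participant_id": pid,
                "time": t,
                "event": event,
                "censor_reason": reason,
                "age": float(base["age"]),
                "education_years": float(base["education_years"]),
                "baseline_score": float(base[col]),
            }
        )
    out = pd.DataFrame(records)
    if subgroups is not None and not out.empty:
        out = out.merge(
            subgroups.reset_index()[["participant_id", "category", "retained"]],
            on="participant_id",
            how="inner",
        )
        out = out[out["retained"]].drop(columns="retained")
        out = out.rename(columns={"category": "subgroup"})
    return out


def _group_design(records: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, list[str]]:
    groups = sorted(records["subgroup"].unique())
    if reference not in groups:
        reference = groups[0]
    dummies = [g for g in groups if g != reference]
    df = records.copy()
    for g in dummies:
        df[f"group_{g}"] = (df["subgroup"] == g).astype(float)
    return df, [f"group_{g}" for g in dummies]


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    reference: str = "NC_both",
    check_ph: bool = True,
) -> CoxFitResult:
    """Cox proportional hazards across subgroups.

    Subgroups enter as indicator covariates against the reference group.
    When the proportional-hazards check flags an adjustment covariate, the
    model is refitted without it (the violating covariate stays reported in
    the verdicts). Returns an ``estimable = False`` result instead of
    raising when there are no events.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    outcome = records.attrs.get("outcome", "")
    if records.empty or records["event"].sum() == 0:
        return CoxFitResult(
            outcome, len(records), 0, pd.DataFrame(), None, None,
            estimable=False, note="no events observed",
        )
    has_groups = "subgroup" in records.columns and records["subgroup"].nunique() > 1
    if has_groups:
        df, group_cols = _group_design(records, reference)
    else:
        df, group_cols = records.copy(), []
    model_cols = group_cols + [c for c in covariates if c in df.columns]
    fit_df = df[["time", "event"] + model_cols].astype(float)

    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="time", event_col="event")

    verdicts: dict[str, str] = {}
    if check_ph and int(fit_df["event"].sum()) >= 3 and model_cols:
        ph = proportional_hazard_test(cph, fit_df, time_transform="rank")
        pvals = ph.summary["p"]
        for cov in model_cols:
            p = float(pvals.loc[cov]) if cov in pvals.index else float(pvals.loc[(cov,)] )
            verdicts[cov] = "violated" if p < 0.05 else "ok"
        bad = [c for c in covariates if verdicts.get(c) == "violated"]
        if bad:
            model_cols = [c for c in model_cols if c not in bad]
            fit_df = df[["time", "event"] + model_cols].astype(float)
            cph = CoxPHFitter()
            cph.fit(fit_df, duration_col="time", event_col="event")

    summ = cph.summary
    coefs = pd.DataFrame(
        {
            "log_hr": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )

    global_p, pairwise = None, None
    if has_groups:
        lr = multivariate_logrank_test(df["time"], df["subgroup"], df["event"])
        global_p = float(lr.p_value)
        pw = pairwise_logrank_test(df["time"], df["subgroup"], df["event"]).summary
        pw = pw.reset_index()
        pw["adjusted_p"] = bh_adjust(pw["p"].to_numpy())
        pairwise = pw
    return CoxFitResult(
        outcome=outcome,
        n=len(records),
        n_events=int(records["event"].sum()),
        coefficients=coefs,
        global_logrank_p=global_p,
        pairwise_logrank=pairwise,
        ph_verdicts=verdicts,
        estimable=True,
    )


def ph_check(records: pd.DataFrame, fitted: CoxPHFitter, fit_df: pd.DataFrame) -> dict:
    """Stand-alone proportional-hazards verdicts for a fitted model."""
    if int(fit_df["event"].sum()) < 3:
        return {}
    cols = [c for c in fit_df.columns if c not in ("time", "event")]
    if not cols:
        return {}
    ph = proportional_hazard_test(fitted, fit_df, time_transform="rank")
    pvals = ph.summary["p"]
    return {
        c: ("violated" if float(pvals.loc[c]) < 0.05 else "ok") for c in cols
    }
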