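"""Cohort eligibility and exclusion rules.

Removes, in a fixed documented order, participants whose cognitive status
could be confounded by conditions unrelated to PD:

1. anyone with a psychiatric (bipolar, schizophrenia) or neurological
   (seizures, stroke, TBI, brain tumour) exclusion, or BDI-I >= 30;
2. healthy controls at risk of developing PD: RBDSQ >= 6, family history,
   or any comorbidity / lifestyle risk flag;
3. PD participants meeting PD-dementia criteria: MoCA below 22 (the MMSE-26
   equivalent) together with a PDQ-39 ADL subscore above 14.

Each participant is counted once, at the first rule that triggers, so the
attrition report sums to the number of rows removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import schema


@dataclass
class EligibilityRuleSet:
    bdi_max_exclusive: int = 30
    rbdsq_hc_min: int = 6
    hc_risk_flags: tuple[str, ...] = tuple(schema.HC_RISK_FLAGS)
    psychiatric_exclusions: tuple[str, ...] = tuple(schema.PSYCHIATRIC_FLAGS)
    neuro_exclusions: tuple[str, ...] = tuple(schema.NEURO_FLAGS)
    pdd_moca_below: int = 22
    pdd_adl_above: int = 14

    def validate(self) -> None:
        for name in ("bdi_max_exclusive", "rbdsq_hc_min", "pdd_moca_below", "pdd_adl_above"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AttritionReport:
    """Removal counts per rule, attributed at the first triggering rule."""

    input_rows: int = 0
    output_rows: int = 0
    removed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "output_rows": self.output_rows,
            "removed": dict(self.removed),
        }


_REQUIRED = ["participant_id", "group", "bdi", "rbdsq", "moca_total"]


def apply_filters(
    table: pd.DataFrame, rules: EligibilityRuleSet | None = None
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply eligibility rules to a baseline table.

    Returns the eligible table and an :class:`AttritionReport`. Raises a
    schema error naming the first missing required column.
    """
    rules = rules or EligibilityRuleSet()
    rules.validate()
    needed = _REQUIRED + list(rules.psychiatric_exclusions) + list(rules.neuro_exclusions)
    for col in needed:
        if col not in table.columns:
            raise KeyError(f"required column missing: {col!r}")
    bad_groups = set(table["group"]) - {"PD", "HC"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    report = AttritionReport(input_rows=len(table))
    if table.empty:
        report.removed = {
            "psychiatric_or_neurological": 0,
            "depression_bdi": 0,
            "hc_risk": 0,
            "pdd": 0,
        }
        return table.copy(), report

    df = table.copy()
    is_hc = df["group"] == "HC"
    is_pd = df["group"] == "PD"

    psych_neuro = pd.Series(False, index=df.index)
    for flag in list(rules.psychiatric_exclusions) + list(rules.neuro_exclusions):
        psych_neuro |= df[flag].fillna(0).astype(float) > 0

    bdi = df["bdi"].astype(float) >= rules.bdi_max_exclusive

    hc_risk = pd.Series(False, index=df.index)
    hc_risk |= df["rbdsq"].astype(float) >= rules.rbdsq_hc_min
    for flag in rules.hc_risk_flags:
        if flag in df.columns:
            hc_risk |= df[flag].fillna(0).astype(float) > 0
    hc_risk &= is_hc

    adl = schema.adl_subscore(df) if set(schema.PDQ_ADL_ITEMS) <= set(df.columns) else 0.0
    pdd = is_pd & (df["moca_total"].astype(float) < rules.pdd_moca_below) & (
        pd.Series(adl, index=df.index).astype(float) > rules.pdd_adl_above
    )

    # first-trigger attribution, in documented order
    removed_psych = psych_neuro
    removed_bdi = bdi & ~removed_psych
    removed_hc = hc_risk & ~removed_psych & ~removed_bdi
    removed_pdd = pdd & ~removed_psych & ~removed_bdi & ~removed_hc

    drop = removed_psych | removed_bdi | removed_hc | removed_pdd
    out = df.loc[~drop].copy()
    report.output_rows = len(out)
    report.removed = {
        "psychiatric_or_neurological": int(removed_psych.sum()),
        "depression_bdi": int(removed_bdi.sum()),
        "hc_risk": int(removed_hc.sum()),
        "pdd": int(removed_pdd.sum()),
    }
    return out, report
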