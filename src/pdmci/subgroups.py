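"""Four-way diagnostic-overlap subgrouping and baseline characterisation.

Crossing the data-driven model's NC/MCI call with the clinical reference
test's yields four subgroups: concordant NC (``NC_both``), concordant MCI
(``MCI_both``), and the two discordant groups — ``ref_only_MCI`` (clinical
MCI missed by the model) and ``model_only_MCI`` (the data-driven early-MCI
candidates the clinical criteria do not capture). Groups smaller than a
minimum size are flagged and excluded from downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mci as mci_mod
from .stats import TestResult, bh_adjust, distributional_test

CATEGORIES = ("NC_both", "ref_only_MCI", "model_only_MCI", "MCI_both")
DEFAULT_MIN_GROUP_SIZE = 5

#: feature -> kind manifest for the baseline characterisation table
DEFAULT_FEATURE_MANIFEST = {
    "age": "numeric",
    "education_years": "numeric",
    "sex": "categorical",
    "moca_total": "numeric",
    "updrs_1_1": "ordinal",
    "updrs_iii": "numeric",
    "hoehn_yahr": "ordinal",
    "disease_duration": "numeric",
    "age_at_onset": "numeric",
    "bdi": "numeric",
    "sas": "numeric",
}


def assign_subgroups(
    model_labels: pd.Series,
    reference_labels: pd.Series,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Cross-tabulated subgroup assignment, indexed by participant.

    Both label series must be indexed by participant id and cover exactly
    the same participants, with values in {"NC", "MCI"}.
    """
    model_labels = pd.Series(model_labels)
    reference_labels = pd.Series(reference_labels)
    if set(model_labels.index) != set(reference_labels.index):
        only = set(model_labels.index) ^ set(reference_labels.index)
        raise ValueError(f"participants present in one labelling only: {sorted(only)[:3]}")
    ref = reference_labels.reindex(model_labels.index)

    def categorise(m, r):
        if m == "NC" and r == "NC":
            return "NC_both"
        if m == "NC" and r == "MCI":
            return "ref_only_MCI"
        if m == "MCI" and r == "NC":
            return "model_only_MCI"
        return "MCI_both"

    cat = pd.Series(
        [categorise(m, r) for m, r in zip(model_labels, ref)], index=model_labels.index
    )
    sizes = cat.value_counts()
    retained = cat.map(lambda c: bool(sizes.get(c, 0) >= min_group_size))
    return pd.DataFrame(
        {"participant_id": cat.index, "category": cat.values, "retained": retained.values}
    ).set_index("participant_id")


def subgroup_sizes(assignments: pd.DataFrame) -> dict:
    return {c: int((assignments["category"] == c).sum()) for c in CATEGORIES}


def characterise_subgroups(
    assignments: pd.DataFrame,
    baseline: pd.DataFrame,
    feature_manifest: dict[str, str] | None = None,
    classified: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise distributional comparisons across retained subgroups.

    For every manifest feature and every retained group pair a routed
    two-group test is run; p-values are Benjamini–Hochberg-adjusted within
    the whole table. When a Level II classification frame is supplied the
    summary also carries per-group domain-impairment and
    none/single/multi-domain profile proportions.
    """
    manifest = feature_manifest or DEFAULT_FEATURE_MANIFEST
    base = baseline.set_index("participant_id") if "participant_id" in baseline.columns else baseline
    retained = assignments[assignments["retained"]]
    cats = [c for c in CATEGORIES if (retained["category"] == c).any()]
    if len(cats) < 2:
        raise ValueError("need at least 2 retained subgroups")

    rows: list[dict] = []
    skipped: list[str] = []
    for feature, kind in manifest.items():
        if feature not in base.columns:
            skipped.append(feature)
            continue
        for i, ca in enumerate(cats):
            for cb in cats[i + 1 :]:
                ids_a = retained.index[retained["category"] == ca]
                ids_b = retained.index[retained["category"] == cb]
                try:
                    res: TestResult = distributional_test(
                        base.loc[ids_a, feature], base.loc[ids_b, feature], feature, kind
                    )
                except (ValueError, ZeroDivisionError) as exc:
                    skipped.append(f"{feature} ({ca} vs {cb}): {exc}")
                    continue
                rows.append(
                    {
                        "feature": feature,
                        "group_a": ca,
                        "group_b": cb,
                        "test": res.test_used,
                        "statistic": res.statistic,
                        "p": res.p,
                        "effect_size": res.effect_size,
                        "effect_size_name": res.effect_size_name,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adjusted_p"] = bh_adjust(table["p"].to_numpy())

    summary: dict = {"sizes": subgroup_sizes(assignments), "skipped": skipped}
    if classified is not None:
        cls = (
            classified.set_index("participant_id")
            if "participant_id" in classified.columns
            else classified
        )
        profiles = {}
        for c in cats:
            ids = retained.index[retained["category"] == c]
            profiles[c] = mci_mod.profile_summary(cls.loc[cls.index.intersection(ids)])
        summary["profiles"] = profiles
    return table, summary
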