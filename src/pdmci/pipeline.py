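"""End-to-end orchestration.

``run_all`` wires the stages together: simulate (or load) -> eligibility
filters -> normative scoring on healthy controls -> Level II reference
classification -> clinically gated clustering -> bootstrap effect-size
comparison -> four-way subgroup assignment and characterisation ->
longitudinal Cox validation. Every stage's outputs are collected in a
results bundle and optionally written as tidy TSV/JSON artefacts with a
manifest containing the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import yaml

from . import cluster, filters, mci, normative, schema, stats, subgroups, survival
from .synthetic import CohortSpec, generate_baseline, generate_followups

COMPARISON_FEATURES = ("moca_total", "updrs_1_1", "pdq39_scc")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the study's published defaults."""

    seed: int = 0
    impairment_threshold: float = -1.5  # z cut-off for test impairment
    min_impaired_tests: int = 2  # Level II rule
    n_clusters: int = 2
    n_boot: int = 10_000
    min_group_size: int = 5
    moca_event_threshold: int = 21  # event: MoCA <= 21
    updrs_event_threshold: int = 3  # event: MDS-UPDRS 1.1 >= 3
    alpha: float = 0.05
    ari_floor: float = 0.1  # declared minimum ARI vs planted NC/impaired split
    rules: filters.EligibilityRuleSet = field(default_factory=filters.EligibilityRuleSet)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "rules":
                cfg.rules = filters.EligibilityRuleSet(**value)
            elif key == "cohort":
                for k, v in value.items():
                    setattr(cfg.cohort, k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


def _stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def run_all(
    config: PipelineConfig | None = None,
    baseline: pd.DataFrame | None = None,
    longitudinal: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    grids: dict | None = None,
) -> dict:
    """Run the full analysis; returns the results bundle as a dict.

    Without input tables a synthetic cohort is generated from
    ``config.cohort`` (seeded from the master seed). Ground truth, when
    available, adds planted-class recovery diagnostics.
    """
    cfg = config or PipelineConfig()
    bundle: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # --- stage 1: cohort ---------------------------------------------------
    if baseline is None:
        spec = cfg.cohort
        spec.seed = _stage_seed(cfg.seed, 1)
        baseline, truth = generate_baseline(spec)
        longitudinal = generate_followups(baseline, truth, spec)
    bundle["n_input"] = len(baseline)

    # --- stage 2: eligibility ----------------------------------------------
    eligible, attrition = filters.apply_filters(baseline, cfg.rules)
    bundle["attrition"] = attrition.to_dict()

    # --- stage 3: normative scoring ----------------------------------------
    controls = eligible[eligible["group"] == "HC"]
    pd_base = eligible[eligible["group"] == "PD"].reset_index(drop=True)
    models = normative.fit_normative_models(controls)
    bundle["normative_models"] = normative.models_to_frame(models)
    z_pd = normative.score_cohort(pd_base, models)
    z_hc = normative.score_cohort(controls, models)
    bundle["z_scores_pd"] = z_pd
    # calibration diagnostic: on the reference sample each test's z should
    # be centred near 0 with SD near 1
    zcols = [schema.z_col(t) for t in models]
    bundle["reference_z_calibration"] = pd.DataFrame(
        {"mean": z_hc[zcols].mean(), "sd": z_hc[zcols].std(ddof=1)}
    )

    # --- stage 4: clinical reference classification ------------------------
    classified = mci.classify_cohort(z_pd, cfg.impairment_threshold)
    bundle["reference_classification"] = classified
    bundle["reference_profile_summary"] = mci.profile_summary(classified)
    ref_labels = pd.Series(
        classified["status"].to_numpy(), index=pd_base["participant_id"].to_numpy()
    )

    # --- stage 5: data-driven model ----------------------------------------
    scored = pd.concat([pd_base, z_pd.drop(columns="participant_id")], axis=1)
    fm = cluster.build_feature_matrix(scored)
    best, report = cluster.grid_search(
        fm, scored, grids=grids, seed=_stage_seed(cfg.seed, 5), select_k=cfg.n_clusters
    )
    bundle["model_selection_report"] = report
    # compare the per-algorithm winners against the clinical reference and
    # keep the most suitable: highest MCI sensitivity, AUC breaking ties
    selected_name, selected, evaluations, best_key = None, None, {}, None
    for name, sol in best.items():
        if sol is None:
            continue
        ev = cluster.evaluate_vs_reference(sol, ref_labels.to_numpy())
        evaluations[name] = ev.to_dict()
        key = (ev.sensitivity, ev.auc if ev.auc is not None else -1.0)
        if best_key is None or key > best_key:
            selected_name, selected, best_key = name, sol, key
    bundle["evaluations"] = evaluations
    if selected is None:
        bundle["no_plausible_solution"] = True
        bundle["note"] = (
            "no clinically plausible clustering solution survived the external "
            "criteria; downstream comparison stages skipped"
        )
        return _write_bundle(bundle, out_dir)
    bundle["selected_algorithm"] = selected_name
    bundle["selected_silhouette"] = selected.silhouette
    bundle["selected_hyperparameters"] = selected.hyperparameters
    bundle["feature_importance"] = cluster.feature_importance(fm, selected.labels)
    model_labels = pd.Series(
        selected.mapped_labels(), index=pd_base["participant_id"].to_numpy()
    )
    bundle["model_labels"] = model_labels

    if truth is not None:
        tr = truth.set_index("participant_id")["latent_class"]
        planted = tr.reindex(model_labels.index)
        planted_binary = (planted != "NC").map({True: "MCI", False: "NC"})
        bundle["ari_vs_planted"] = float(
            adjusted_rand_score(planted_binary, model_labels)
        )
        bundle["ari_floor"] = cfg.ari_floor

    # --- stage 6: effect-size comparison ------------------------------------
    comp_base = pd_base.assign(pdq39_scc=schema.scc_subscore(pd_base))
    comparisons = []
    boot_seed = _stage_seed(cfg.seed, 6)
    for i, feat in enumerate(COMPARISON_FEATURES):
        res = stats.bootstrap_effectsize_difference(
            comp_base[feat].to_numpy(),
            model_labels.to_numpy(),
            ref_labels.to_numpy(),
            feature=feat,
            n_boot=cfg.n_boot,
            seed=boot_seed + i,
        )
        comparisons.append(dataclasses.asdict(res))
    comp_df = pd.DataFrame(comparisons)
    comp_df["adjusted_p"] = stats.bh_adjust(comp_df["boot_p"].to_numpy())
    bundle["effect_size_comparison"] = comp_df

    # --- stage 7: subgroups --------------------------------------------------
    assignments = subgroups.assign_subgroups(model_labels, ref_labels, cfg.min_group_size)
    bundle["subgroup_assignments"] = assignments
    bundle["subgroup_sizes"] = subgroups.subgroup_sizes(assignments)
    char_table, char_summary = subgroups.characterise_subgroups(
        assignments, pd_base, classified=classified.assign(
            participant_id=pd_base["participant_id"].to_numpy()
        ),
    )
    bundle["subgroup_characterisation"] = char_table
    bundle["subgroup_summary"] = char_summary

    # --- stage 8: longitudinal validation ------------------------------------
    bundle["survival"] = {}
    if longitudinal is not None:
        for outcome in ("moca", "updrs_1_1"):
            records = survival.derive_events(longitudinal, outcome, assignments)
            records.attrs["outcome"] = outcome
            fit = survival.cox_fit(records)
            bundle["survival"][outcome] = {
                "n": fit.n,
                "n_events": fit.n_events,
                "estimable": fit.estimable,
                "global_logrank_p": fit.global_logrank_p,
                "coefficients": fit.coefficients,
                "pairwise_logrank": fit.pairwise_logrank,
                "ph_verdicts": fit.ph_verdicts,
            }
    return _write_bundle(bundle, out_dir)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_bundle(bundle: dict, out_dir) -> dict:
    if out_dir is None:
        return bundle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.tsv", sep="\t", index=True)
        elif isinstance(value, pd.Series):
            value.rename(key).to_csv(out / f"{key}.tsv", sep="\t")
    manifest = {k: _jsonable(v) for k, v in bundle.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle
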